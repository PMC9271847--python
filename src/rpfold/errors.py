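"""Exception hierarchy for the random-permutant pipeline.

Every stage raises a subclass of :class:`RPError` so that the pipeline
driver can attach stage provenance without string-matching messages.
"""


class RPError(Exception):
    """Base class for all rpfold errors."""


# --- structure I/O ---------------------------------------------------------

class NoChainFound(RPError):
    pass


class NonStandardResidue(RPError):
    def __init__(self, resname: str, position):
        self.resname = resname
        self.position = position
        super().__init__(f"non-standard residue {resname!r} at position {position}")


class MissingBackboneAtom(RPError):
    def __init__(self, residue_index: int, atom: str = ""):
        self.residue_index = residue_index
        self.atom = atom
        super().__init__(f"residue {residue_index} is missing backbone atom {atom or '?'}")


class InvalidSpec(RPError):
    pass


# --- repack ---------------------------------------------------------------

class InvalidAlphabet(RPError):
    pass


class LengthMismatch(RPError):
    pass


class ExternalToolFailure(RPError):
    pass


# --- contacts -------------------------------------------------------------

class MissingCA(RPError):
    def __init__(self, residue_index: int):
        self.residue_index = residue_index
        super().__init__(f"residue {residue_index} has no CA atom")


class IncompatibleSizes(RPError):
    pass


class EmptyContactMap(RPError):
    pass


# --- sbm ------------------------------------------------------------------

class ContactSizeMismatch(RPError):
    pass


class ShapeMismatch(RPError):
    pass


# --- dynamics -------------------------------------------------------------

class NumericalBlowup(RPError):
    pass


class NoFoldingDetected(RPError):
    pass


class NoUnfoldingDetected(RPError):
    pass


# --- landscape ------------------------------------------------------------

class DegenerateWeights(UserWarning):
    """Effective sample size collapsed during histogram reweighting."""


class AllBinsEmpty(RPError):
    pass


class NoTwoBasins(RPError):
    pass


class EmptyBin(RPError):
    pass


class ZeroVariance(RPError):
    """Route similarity undefined: at least one formation vector is constant."""


# --- robustness -----------------------------------------------------------

class UnconvergedInput(RPError):
    pass


class NoImprovedRP(RPError):
    pass


class StageError(RPError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
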