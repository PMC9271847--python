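"""Protein structure containers, PDB I/O, and synthetic toy structures.

PDB parsing and writing go through :mod:`gemmi`; this module is a thin
domain layer that normalizes structures into the simple residue/atom model
the rest of the pipeline consumes: sequential 1..N residue numbering, one
location per atom, no heteroatoms or waters.

The toy builder produces small idealized alpha/beta structures (helices,
strands, hairpins, packed assemblies) from internal coordinates so that
every downstream stage — repacking, contact maps, structure-based models,
folding runs — can be exercised on synthetic inputs.
"""
from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import gemmi
import numpy as np

from . import rotamers
from .errors import (InvalidSpec, MissingBackboneAtom, NoChainFound,
                     NonStandardResidue)
from .geometry import place_atom

__all__ = [
    "Atom", "Residue", "ProteinStructure", "BackboneScaffold", "ToySpec",
    "Segment", "read_structure", "write_structure", "extract_backbone",
    "strip_hydrogens", "make_toy_structure", "find_missing_atoms",
]


@dataclasses.dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray            # A
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")

    @property
    def is_hydrogen(self) -> bool:
        """Element-based hydrogen test; falls back to the PDB naming
        convention (optional leading digit then 'H') when no element is set."""
        el = self.element.strip()
        if el:
            return el.upper() in ("H", "D")
        name = self.name.strip().lstrip("0123456789")
        return name.startswith("H")


@dataclasses.dataclass
class Residue:
    index: int                    # 1-based sequential
    aa: str                       # one-letter code
    atoms: list[Atom] = dataclasses.field(default_factory=list)
    author_number: int | None = None

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def has_backbone(self) -> bool:
        counts = [sum(1 for a in self.atoms if a.name == n)
                  for n in rotamers.BACKBONE_ATOMS]
        return counts == [1, 1, 1, 1]

    def sidechain_atoms(self) -> list[Atom]:
        bb = set(rotamers.BACKBONE_ATOMS) | {"OXT"}
        return [a for a in self.atoms if a.name not in bb]


@dataclasses.dataclass
class ProteinStructure:
    residues: list[Residue]
    label: str = ""

    def __post_init__(self):
        if len(self.residues) < 2:
            raise ValueError("a structure needs at least 2 residues")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        """(N, 3) array of Calpha positions in A."""
        out = np.empty((self.n_residues, 3))
        for k, r in enumerate(self.residues):
            ca = r.atom("CA")
            if ca is None:
                from .errors import MissingCA
                raise MissingCA(r.index)
            out[k] = ca.coords
        return out

    def heavy_atoms(self) -> list[tuple[int, Atom]]:
        """(residue index, atom) pairs for all non-hydrogen atoms."""
        return [(r.index, a) for r in self.residues for a in r.atoms
                if not a.is_hydrogen]

    def copy(self) -> "ProteinStructure":
        res = [Residue(r.index, r.aa,
                       [Atom(a.name, a.element, a.coords.copy(), a.occupancy,
                             a.altloc) for a in r.atoms],
                       r.author_number)
               for r in self.residues]
        return ProteinStructure(res, self.label)


class BackboneScaffold(ProteinStructure):
    """A structure stripped to the four backbone atoms N, CA, C, O."""


# ---------------------------------------------------------------------------
# PDB I/O

_WATERS = {"HOH", "WAT", "DOD"}


def read_structure(pdb_text: str, chain: str | None = None,
                   label: str = "") -> ProteinStructure:
    """Parse PDB text into a normalized :class:`ProteinStructure`.

    Keeps the requested chain (default: the first chain containing amino
    acids) of the first model. Waters and non-polymer HETATM records are
    dropped; common modified residues are mapped to their parent amino
    acid; alternate locations are resolved to the highest-occupancy copy
    (ties broken by the lexicographically first altloc id); residues are
    renumbered sequentially 1..N with the author numbering kept as
    metadata.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise NoChainFound("no model in PDB text")
    model = st[0]
    known = set(rotamers.AA3_TO_1) | set(rotamers.MODIFIED_PARENT)

    def chain_residues(ch):
        # HETATM ligands and waters are dropped; ATOM records with an
        # unrecognized residue name survive to raise NonStandardResidue
        return [res for res in ch
                if res.name in known
                or (res.het_flag == "A" and res.name not in _WATERS)]

    selected = None
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        if chain_residues(ch):
            selected = ch
            break
    if selected is None:
        raise NoChainFound(f"chain {chain!r}" if chain is not None
                           else "no chain with standard amino acids")

    residues: list[Residue] = []
    for pos, res in enumerate(chain_residues(selected), start=1):
        name = res.name
        if name in rotamers.MODIFIED_PARENT:
            name = rotamers.MODIFIED_PARENT[name]
        if name not in rotamers.AA3_TO_1:
            raise NonStandardResidue(res.name, pos)
        aa = rotamers.AA3_TO_1[name]
        # altloc resolution: group by atom name, keep best copy
        by_name: dict[str, list[gemmi.Atom]] = {}
        for at in res:
            by_name.setdefault(at.name, []).append(at)
        atoms = []
        for atname, copies in by_name.items():
            best = min(copies, key=lambda a: (-a.occ, a.altloc or "~"))
            atoms.append(Atom(atname, best.element.name,
                              np.array([best.pos.x, best.pos.y, best.pos.z]),
                              best.occ, best.altloc or ""))
        residues.append(Residue(pos, aa, atoms, author_number=res.seqid.num))

    # drop residues that failed above; by construction all kept are standard
    hetatm_free = [r for r in residues]
    if len(hetatm_free) < 2:
        raise NoChainFound("fewer than 2 standard residues in selected chain")
    return ProteinStructure(hetatm_free, label or st.name or "structure")


def write_structure(s: ProteinStructure, chain_name: str = "A") -> str:
    """Serialize to fixed-column PDB text (ATOM/TER/END) via gemmi."""
    st = gemmi.Structure()
    st.name = s.label or "rpfold"
    model = gemmi.Model("1")
    ch = gemmi.Chain(chain_name)
    for r in s.residues:
        gres = gemmi.Residue()
        gres.name = rotamers.AA1_TO_3[r.aa]
        gres.seqid = gemmi.SeqId(r.index, " ")
        for a in r.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element or "X")
            ga.pos = gemmi.Position(*a.coords)
            ga.occ = a.occupancy
            ga.altloc = a.altloc or "\0"
            gres.add_atom(ga)
        ch.add_residue(gres)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


def strip_hydrogens(s: ProteinStructure) -> ProteinStructure:
    out = s.copy()
    for r in out.residues:
        r.atoms = [a for a in r.atoms if not a.is_hydrogen]
    return out


def extract_backbone(s: ProteinStructure) -> BackboneScaffold:
    """Delete all side-chain atoms, keeping exactly N, CA, C, O per residue."""
    residues = []
    for r in s.residues:
        atoms = []
        for name in rotamers.BACKBONE_ATOMS:
            a = r.atom(name)
            if a is None:
                raise MissingBackboneAtom(r.index, name)
            atoms.append(Atom(a.name, a.element or name[0], a.coords.copy()))
        residues.append(Residue(r.index, r.aa, atoms, r.author_number))
    return BackboneScaffold(residues, s.label)


def find_missing_atoms(s: ProteinStructure) -> list[tuple[int, str]]:
    """Census of heavy atoms expected for each residue's type but absent.

    Backbone N/CA/C/O plus the standard side-chain composition are
    required; OXT is optional and never reported.
    """
    missing = []
    for r in s.residues:
        present = {a.name for a in r.atoms}
        expected = list(rotamers.BACKBONE_ATOMS) + list(rotamers.SIDECHAIN_ATOMS[r.aa])
        for name in expected:
            if name not in present:
                missing.append((r.index, name))
    return missing


# ---------------------------------------------------------------------------
# Toy structures

_PHI_PSI = {
    "helix": (-57.0, -47.0),
    "strand": (-139.0, 135.0),
    "loop": (-75.0, 150.0),
}

# two-residue beta-turn torsions used when a short loop joins two paired
# strands; tuned once so ideal-geometry hairpins close in register with
# cross-strand CA-CA distances near 4.5-5 A and no backbone collisions
_TURN = [(-60.0, 10.0), (-160.0, -30.0)]

# standard peptide geometry (A, deg)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8


@dataclasses.dataclass
class Segment:
    kind: str                     # helix | strand | loop
    length: int
    sequence: str

    def __post_init__(self):
        if self.kind not in _PHI_PSI:
            raise InvalidSpec(f"unknown segment kind {self.kind!r}")
        if len(self.sequence) != self.length:
            raise InvalidSpec("segment sequence length mismatch")
        bad = set(self.sequence) - set(rotamers.AA1_TO_3)
        if bad:
            raise InvalidSpec(f"invalid amino acids {sorted(bad)}")


@dataclasses.dataclass
class ToySpec:
    """Recipe for a synthetic structure.

    ``assembly`` entries:
      ("pair", i, j)           — segments i and j are hairpin-paired strands
                                 (the loop between them gets turn torsions)
      ("pack", i, j[, gap])    — optimize the torsions of the free loop
                                 segments between i and j so segment group i
                                 packs against group j (compact,
                                 collision-free); i and j may be tuples of
                                 segment indices, and a nonzero gap keeps
                                 the groups at least that far apart (CA-CA)
    """
    segments: list[Segment]
    assembly: list[tuple] = dataclasses.field(default_factory=list)
    label: str = "toy"

    @property
    def sequence(self) -> str:
        return "".join(seg.sequence for seg in self.segments)

    @property
    def length(self) -> int:
        return sum(seg.length for seg in self.segments)


def _segment_ranges(spec: ToySpec) -> list[tuple[int, int]]:
    ranges, start = [], 0
    for seg in spec.segments:
        ranges.append((start, start + seg.length))
        start += seg.length
    return ranges


def _default_torsions(spec: ToySpec) -> list[tuple[float, float]]:
    tors: list[tuple[float, float]] = []
    ranges = _segment_ranges(spec)
    for seg in spec.segments:
        tors.extend([_PHI_PSI[seg.kind]] * seg.length)
    # hairpin turns: a loop of length <= 3 between paired strands
    for entry in spec.assembly:
        if entry[0] != "pair":
            continue
        _, i, j = entry
        for k in range(min(i, j) + 1, max(i, j)):
            if spec.segments[k].kind == "loop" and spec.segments[k].length <= 3:
                lo, hi = ranges[k]
                for n, idx in enumerate(range(lo, hi)):
                    tors[idx] = _TURN[min(n, len(_TURN) - 1)]
    return tors


def _build_backbone(torsions: Sequence[tuple[float, float]]) -> np.ndarray:
    """N/CA/C/O positions from (phi, psi) per residue, omega fixed at 180.

    Returns an (N, 4, 3) array ordered N, CA, C, O.
    """
    n = len(torsions)
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    # seed the first residue explicitly
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    C[0] = place_atom(np.array([0.0, 1.0, 0.0]), N[0], CA[0],
                      _B_CA_C, _A_N_CA_C, 60.0)
    for i in range(1, n):
        psi_prev = torsions[i - 1][1]
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N,
                          psi_prev)
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA,
                           180.0)  # omega
        phi = torsions[i][0]
        C[i] = place_atom(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi)
    O = np.zeros((n, 3))
    for i in range(n):
        psi = torsions[i][1] if i < n - 1 else 180.0
        O[i] = place_atom(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi + 180.0)
    return np.stack([N, CA, C, O], axis=1)


def _scaffold_from_backbone(bb: np.ndarray, sequence: str,
                            label: str) -> BackboneScaffold:
    residues = []
    for i, aa in enumerate(sequence):
        atoms = [Atom(name, name[0], bb[i, k])
                 for k, name in enumerate(rotamers.BACKBONE_ATOMS)]
        residues.append(Residue(i + 1, aa, atoms))
    return BackboneScaffold(residues, label)


def _compactness_score(bb: np.ndarray, rng_i: tuple[int, int],
                       rng_j: tuple[int, int], gap: float = 0.0) -> float:
    """Packing objective for loop optimization: mean CA-CA distance between
    the two segments plus a steep penalty for backbone collisions. A
    nonzero ``gap`` forbids the segments from approaching closer than that
    CA-CA distance (used to build interfaces only long side chains span)."""
    ca = bb[:, 1, :]
    a = np.concatenate([ca[lo:hi] for lo, hi in rng_i])
    b = np.concatenate([ca[lo:hi] for lo, hi in rng_j])
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    lo_edge = max(4.2, gap)
    # maximize the inter-group interface: CA pairs in the contact window,
    # with the mean separation as a weak tie-breaker
    n_window = int(np.count_nonzero((d > lo_edge) & (d < 7.0)))
    score = -float(n_window) + 0.02 * float(d.mean())
    if gap > 0.0:
        score += 50.0 * max(0.0, gap - float(d.min()))
    # chain-collision penalty on CA beads of non-adjacent residues
    nres = bb.shape[0]
    dd = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    sep = np.abs(np.arange(nres)[:, None] - np.arange(nres)[None, :])
    clash = (dd < 3.6) & (sep >= 2)
    score += 25.0 * (np.count_nonzero(clash) // 2)
    return score


def _optimize_packing(spec: ToySpec, torsions: list[tuple[float, float]],
                      rng: np.random.Generator) -> list[tuple[float, float]]:
    ranges = _segment_ranges(spec)
    grid = [-150.0, -120.0, -90.0, -60.0, 60.0, 100.0, 150.0]
    turn_loops: set[int] = set()
    for entry in spec.assembly:
        if entry[0] == "pair":
            for k in range(min(entry[1], entry[2]) + 1,
                           max(entry[1], entry[2])):
                if spec.segments[k].kind == "loop":
                    turn_loops.add(k)
    claimed: set[int] = set(turn_loops)
    for entry in spec.assembly:
        if entry[0] != "pack":
            continue
        movers = entry[1] if isinstance(entry[1], (tuple, list)) else (entry[1],)
        targets = entry[2] if isinstance(entry[2], (tuple, list)) else (entry[2],)
        gap = float(entry[3]) if len(entry) > 3 else 0.0
        imin, jmin = min(movers), min(targets)
        free = [k for k in range(min(imin, jmin) + 1, max(imin, jmin))
                if spec.segments[k].kind == "loop" and k not in claimed]
        claimed.update(free)
        loop_idx = [idx for k in free for idx in range(*ranges[k])]
        if not loop_idx:
            continue
        mov_ranges = [ranges[i] for i in movers]
        tgt_ranges = [ranges[j] for j in targets]
        # joint seeded random search over the loop torsions (single-torsion
        # moves cannot cross between packing arrangements), then one
        # coordinate-descent polishing sweep
        best = _compactness_score(_build_backbone(torsions),
                                  mov_ranges, tgt_ranges, gap)
        n_trials = 1500
        for _ in range(n_trials):
            trial = list(torsions)
            for idx in loop_idx:
                trial[idx] = (float(rng.choice(grid)), float(rng.choice(grid)))
            sc = _compactness_score(_build_backbone(trial),
                                    mov_ranges, tgt_ranges, gap)
            if sc < best - 1e-9:
                best = sc
                torsions = trial
        for idx in loop_idx:
            for phi, psi in itertools.product(grid, grid):
                trial = list(torsions)
                trial[idx] = (phi, psi)
                sc = _compactness_score(_build_backbone(trial),
                                        mov_ranges, tgt_ranges, gap)
                if sc < best - 1e-9:
                    best = sc
                    torsions = trial
    return torsions


def make_toy_structure(spec: ToySpec, seed: int = 0) -> ProteinStructure:
    """Build a synthetic structure with side chains from a :class:`ToySpec`.

    The backbone comes from ideal internal coordinates (helix phi/psi =
    -57/-47, strand -139/+135, standard bond lengths and angles); side
    chains are added by the clash-minimizing rotamer placer. Deterministic
    for a fixed (spec, seed).
    """
    if spec.length < 2:
        raise InvalidSpec("toy needs at least 2 residues")
    rng = np.random.default_rng(seed)
    torsions = _default_torsions(spec)
    # small seeded jitter on free-loop torsions makes distinct-seed toys distinct
    ranges = _segment_ranges(spec)
    paired_or_packed_loops: set[int] = set()
    for entry in spec.assembly:
        iis = entry[1] if isinstance(entry[1], (tuple, list)) else (entry[1],)
        js = entry[2] if isinstance(entry[2], (tuple, list)) else (entry[2],)
        for i in iis:
            for j in js:
                for k in range(min(i, j) + 1, max(i, j)):
                    paired_or_packed_loops.add(k)
    for k, seg in enumerate(spec.segments):
        if seg.kind == "loop" and k not in paired_or_packed_loops:
            lo, hi = ranges[k]
            for idx in range(lo, hi):
                dphi, dpsi = rng.uniform(-8.0, 8.0, size=2)
                phi, psi = torsions[idx]
                torsions[idx] = (phi + dphi, psi + dpsi)
    torsions = _optimize_packing(spec, torsions, rng)
    bb = _build_backbone(torsions)
    scaffold = _scaffold_from_backbone(bb, spec.sequence, spec.label)
    from .repack import RepackSettings, repack_side_chains
    return repack_side_chains(scaffold, spec.sequence, RepackSettings())
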