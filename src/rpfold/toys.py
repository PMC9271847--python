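"""Ready-made synthetic study systems.

Small synthetic folds with opposite packing phenotypes, plus the
hairpin/helix fixtures the unit tests build on.

``balanced_toy``
    A 36-residue three-helix bundle with leucine-rich faces everywhere:
    every interface is sustained by many interchangeable medium/large
    residues, so random permutation barely perturbs the contact map —
    the scaffold analogue of a robust design.

``bulky_core_toy``
    The same bundle architecture, but two helices pack a small-residue
    subcore while the third docks across a gap only its concentrated
    large residues (Leu/Phe) can span. Permutation dilutes the larges
    over the chain and the docking interface decays — a miniature of a
    natural fold whose core packs several large aromatics against each
    other.

All builders are deterministic for a fixed seed.
"""
from __future__ import annotations

from .structure_io import ProteinStructure, Segment, ToySpec, make_toy_structure

__all__ = ["balanced_toy_spec", "bulky_core_toy_spec", "balanced_toy",
           "bulky_core_toy", "hairpin_spec", "hairpin_toy",
           "helix_spec", "helix_toy"]


def hairpin_spec(strand_len: int = 6, seq: str | None = None) -> ToySpec:
    """Minimal two-strand hairpin used throughout the unit tests."""
    if seq is None:
        # glycines at the inward-pointing positions near the turn keep the
        # tightly registered ideal-geometry hairpin sterically clean
        seq = ("VTVGVG" if strand_len == 6
               else ("VT" * strand_len)[:strand_len]) + "GG" + \
              ("TV" * strand_len)[:strand_len]
    n = strand_len
    return ToySpec([Segment("strand", n, seq[:n]),
                    Segment("loop", 2, seq[n:n + 2]),
                    Segment("strand", n, seq[n + 2:])],
                   assembly=[("pair", 0, 2)], label="hairpin")


def hairpin_toy(seed: int = 0, **kw) -> ProteinStructure:
    return make_toy_structure(hairpin_spec(**kw), seed)


def helix_spec(length: int = 10, seq: str | None = None) -> ToySpec:
    return ToySpec([Segment("helix", length, seq or "A" * length)],
                   label="helix")


def helix_toy(seed: int = 0, **kw) -> ProteinStructure:
    return make_toy_structure(helix_spec(**kw), seed)


def balanced_toy_spec() -> ToySpec:
    return ToySpec(
        [Segment("helix", 11, "LLKLLELLKLL"),
         Segment("loop", 3, "GSG"),
         Segment("helix", 11, "LLELLKLLELL"),
         Segment("loop", 3, "GSG"),
         Segment("helix", 11, "LLKLLELLKLL")],
        assembly=[("pack", 2, 0), ("pack", 4, (0, 2))],
        label="balanced")


def balanced_toy(seed: int = 0) -> ProteinStructure:
    """39-residue three-helix bundle with size-uniform leucine-rich
    packing: every interface is sustained by abundant interchangeable
    medium/large side chains, so shuffling the sequence barely changes
    the contact map."""
    return make_toy_structure(balanced_toy_spec(), seed)


def bulky_core_toy_spec() -> ToySpec:
    return ToySpec(
        [Segment("helix", 11, "ASVATSVASTV"),
         Segment("loop", 3, "GSG"),
         Segment("helix", 11, "TSAVSTAVSAV"),
         Segment("loop", 3, "GSG"),
         Segment("helix", 11, "LFLLFALLFLL")],
        assembly=[("pack", 2, 0), ("pack", 4, (0, 2), 5.5)],
        label="bulky_core")


def bulky_core_toy(seed: int = 0) -> ProteinStructure:
    """39-residue bundle of the same architecture whose third helix
    docks across a gap that only its concentrated large residues
    (Leu/Phe) can span; the other two helices pack a small-residue
    subcore. Random permutation dilutes the larges over the chain,
    stripping the docking interface while over-packing the subcore — a
    packing-sensitive core in miniature."""
    return make_toy_structure(bulky_core_toy_spec(), seed)
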