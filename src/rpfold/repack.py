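"""Sequence permutation and clash-minimizing side-chain repacking.

The repacker threads a sequence onto a fixed backbone: side chains are
grown from internal-coordinate templates (:mod:`rpfold.rotamers`), with
chi1/chi2 sampled over the discrete set {-60, 60, 180} degrees and deeper
torsions extended. Residues are placed greedily in descending side-chain
size order, each taking the rotamer with the fewest steric clashes against
the backbone and previously placed side chains (ties broken by rotamer
index), followed by refinement sweeps. Only repulsive sterics are scored —
attractive physico-chemical terms are deliberately ignored, so chemically
incompatible neighborhoods are still packed at full density.

An external repacker executable (SCWRL4-compatible invocation) can be
plugged in via :class:`RepackSettings.external_tool`; its output is
validated for backbone preservation on read-back.
"""
from __future__ import annotations

import dataclasses
import itertools
import subprocess
import tempfile
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from . import rotamers
from .errors import (ExternalToolFailure, InvalidAlphabet, LengthMismatch)
from .geometry import place_atom
from .structure_io import (Atom, BackboneScaffold, ProteinStructure, Residue,
                           read_structure, write_structure)

__all__ = [
    "PermutationRecord", "RepackSettings", "permute_sequence",
    "repack_side_chains", "count_clashes", "probe_homopolymer",
    "complete_missing_side_chains",
]


@dataclasses.dataclass
class PermutationRecord:
    source_sequence: str
    permuted_sequence: str
    seed: int
    mapping: np.ndarray   # mapping[k] = source position (0-based) at output k

    def __post_init__(self):
        if sorted(self.permuted_sequence) != sorted(self.source_sequence):
            raise ValueError("permuted sequence is not a rearrangement")


@dataclasses.dataclass
class RepackSettings:
    clash_distance: float = 2.5      # A
    max_sweeps: int = 2
    external_tool: str | None = None

    def __post_init__(self):
        if self.clash_distance <= 0:
            raise ValueError("clash_distance must be positive")


def permute_sequence(seq: str, seed: int) -> PermutationRecord:
    """Uniform random shuffle of the sequence, driven only by the seed.

    The amino-acid multiset is conserved by construction.
    """
    if len(seq) < 1:
        raise InvalidAlphabet("empty sequence")
    bad = set(seq) - set(rotamers.AA1_TO_3)
    if bad:
        raise InvalidAlphabet(f"invalid amino acids {sorted(bad)}")
    rng = np.random.default_rng(seed)
    mapping = rng.permutation(len(seq))
    permuted = "".join(seq[k] for k in mapping)
    return PermutationRecord(seq, permuted, seed, mapping)


# ---------------------------------------------------------------------------
# clash counting

_BB_SET = set(rotamers.BACKBONE_ATOMS) | {"OXT"}


def _excluded(res_i: int, name_i: str, aa_i: str,
              res_j: int, name_j: str, aa_j: str) -> bool:
    """Steric-count exclusions: intra-residue pairs, and covalent/1-3
    neighborhoods across the peptide bond (backbone-backbone pairs of
    adjacent residues, plus the proline CD ring closure onto the preceding
    carbonyl)."""
    if res_i == res_j:
        return True
    if abs(res_i - res_j) != 1:
        return False
    if name_i in _BB_SET and name_j in _BB_SET:
        return True
    # proline N-CD ring puts CD ~2.4 A from the upstream carbonyl carbon
    lo, hi = ((res_i, name_i, aa_i), (res_j, name_j, aa_j))
    if lo[0] > hi[0]:
        lo, hi = hi, lo
    if hi[2] == "P" and hi[1] == "CD" and lo[1] in _BB_SET:
        return True
    return False


def count_clashes(s: ProteinStructure, threshold: float = 2.5) -> int:
    """Number of unordered heavy-atom pairs closer than ``threshold`` A,
    excluding intra-residue and peptide-bond-adjacent backbone pairs."""
    entries = []   # (res_index, name, aa, coords)
    for r in s.residues:
        for a in r.atoms:
            if not a.is_hydrogen:
                entries.append((r.index, a.name, r.aa, a.coords))
    if len(entries) < 2:
        return 0
    pts = np.array([e[3] for e in entries])
    tree = cKDTree(pts)
    count = 0
    for i, j in tree.query_pairs(threshold):
        ri, ni, ai, _ = entries[i]
        rj, nj, aj, _ = entries[j]
        if not _excluded(ri, ni, ai, rj, nj, aj):
            count += 1
    return count


# ---------------------------------------------------------------------------
# rotamer construction

def _rotamer_atoms(aa: str, frame: dict[str, np.ndarray],
                   chis: tuple[float, ...]) -> list[Atom]:
    """Grow the side chain of ``aa`` from a backbone frame {N, CA, C}."""
    coords = dict(frame)
    atoms = []
    for entry in rotamers.SIDECHAIN_ZMATRIX[aa]:
        kind = entry.dihedral[0]
        if kind == "fixed":
            dih = entry.dihedral[1]
        else:
            _, k, offset = entry.dihedral
            dih = chis[k - 1] + offset
        a, b, c = (coords[n] for n in entry.refs)
        pos = place_atom(a, b, c, entry.bond, entry.angle, dih)
        coords[entry.name] = pos
        atoms.append(Atom(entry.name, entry.element, pos))
    return atoms


def _rotamer_set(aa: str) -> list[tuple[float, ...]]:
    n = rotamers.N_CHI[aa]
    if n == 0:
        return [()]
    return list(itertools.product(rotamers.CHI_CHOICES, repeat=n))


def _clashes_against(cand: list[Atom], cand_res: int, cand_aa: str,
                     env_pts: np.ndarray, env_meta: list[tuple[int, str, str]],
                     tree: cKDTree, threshold: float) -> int:
    n = 0
    for a in cand:
        for j in tree.query_ball_point(a.coords, threshold):
            rj, nj, aj = env_meta[j]
            if not _excluded(cand_res, a.name, cand_aa, rj, nj, aj):
                n += 1
    return n


def repack_side_chains(b: BackboneScaffold, seq: str,
                       settings: RepackSettings | None = None) -> ProteinStructure:
    """Thread ``seq`` onto the backbone and rebuild all side chains.

    Backbone coordinates are preserved exactly. Deterministic for fixed
    inputs. When ``settings.external_tool`` is set the work is delegated to
    the external repacker and the result validated on read-back.
    """
    settings = settings or RepackSettings()
    if len(seq) != b.n_residues:
        raise LengthMismatch(f"sequence length {len(seq)} != backbone "
                             f"{b.n_residues}")
    bad = set(seq) - set(rotamers.AA1_TO_3)
    if bad:
        raise InvalidAlphabet(f"invalid amino acids {sorted(bad)}")

    if settings.external_tool:
        return _repack_external(b, seq, settings)

    # start from bare backbone with the new sequence
    residues = []
    for i, r in enumerate(b.residues):
        atoms = [Atom(a.name, a.element, a.coords.copy())
                 for a in r.atoms if a.name in _BB_SET]
        residues.append(Residue(r.index, seq[i], atoms, r.author_number))
    frames = []
    for r in residues:
        frames.append({n: r.atom(n).coords for n in ("N", "CA", "C")})

    order = sorted(range(len(residues)),
                   key=lambda i: (-rotamers.SIDECHAIN_SIZE[seq[i]], i))
    chosen: dict[int, tuple[float, ...]] = {}

    def environment(exclude: int):
        pts, meta = [], []
        for k, r in enumerate(residues):
            for a in r.atoms:
                if k == exclude and a.name not in _BB_SET:
                    continue
                pts.append(a.coords)
                meta.append((r.index, a.name, r.aa))
        return np.array(pts), meta

    def place(i: int):
        aa = seq[i]
        rotset = _rotamer_set(aa)
        if len(rotset) == 1:
            best = rotset[0]
        else:
            env_pts, env_meta = environment(exclude=i)
            tree = cKDTree(env_pts)
            best, best_n = None, None
            for chis in rotset:
                cand = _rotamer_atoms(aa, frames[i], chis)
                n = _clashes_against(cand, residues[i].index, aa,
                                     env_pts, env_meta, tree,
                                     settings.clash_distance)
                if best_n is None or n < best_n:
                    best, best_n = chis, n
        chosen[i] = best
        bb_atoms = [a for a in residues[i].atoms if a.name in _BB_SET]
        residues[i].atoms = bb_atoms + _rotamer_atoms(aa, frames[i], best)

    for sweep in range(max(1, settings.max_sweeps)):
        for i in order:
            if sweep == 0 or rotamers.N_CHI[seq[i]] > 0:
                place(i)

    out = ProteinStructure(residues, b.label)
    return out


def complete_missing_side_chains(s: ProteinStructure,
                                 settings: RepackSettings | None = None
                                 ) -> ProteinStructure:
    """Rebuild only the residues with missing heavy atoms, constrained to
    the structure's own sequence; complete residues keep their original
    side-chain coordinates (a built-in stand-in for structure-repair
    tools used on incomplete crystallographic models)."""
    from .structure_io import find_missing_atoms
    settings = settings or RepackSettings()
    incomplete = {idx for idx, _ in find_missing_atoms(s)}
    if not incomplete:
        return s.copy()
    out = s.copy()
    frames = {}
    for r in out.residues:
        if r.index in incomplete:
            r.atoms = [a for a in r.atoms if a.name in _BB_SET]
            frames[r.index] = {n: r.atom(n).coords for n in ("N", "CA", "C")}

    def environment():
        pts, meta = [], []
        for r in out.residues:
            for a in r.atoms:
                pts.append(a.coords)
                meta.append((r.index, a.name, r.aa))
        return np.array(pts), meta

    order = sorted(incomplete,
                   key=lambda i: (-rotamers.SIDECHAIN_SIZE[out.residues[i - 1].aa], i))
    for _sweep in range(max(1, settings.max_sweeps)):
        for idx in order:
            res = out.residues[idx - 1]
            res.atoms = [a for a in res.atoms if a.name in _BB_SET]
            rotset = _rotamer_set(res.aa)
            if len(rotset) == 1:
                best = rotset[0]
            else:
                env_pts, env_meta = environment()
                tree = cKDTree(env_pts)
                best, best_n = None, None
                for chis in rotset:
                    cand = _rotamer_atoms(res.aa, frames[idx], chis)
                    ncl = _clashes_against(cand, idx, res.aa, env_pts,
                                           env_meta, tree,
                                           settings.clash_distance)
                    if best_n is None or ncl < best_n:
                        best, best_n = chis, ncl
            res.atoms += _rotamer_atoms(res.aa, frames[idx], best)
    return out


def probe_homopolymer(b: BackboneScaffold, aa: str,
                      settings: RepackSettings | None = None) -> ProteinStructure:
    """Repack with a single-residue-type sequence (poly-ALA floor probe,
    poly-TRP/ARG ceiling probe, poly-LEU average-size probe, ...)."""
    if aa not in rotamers.AA1_TO_3:
        raise InvalidAlphabet(f"invalid amino acid {aa!r}")
    return repack_side_chains(b, aa * b.n_residues, settings)


# ---------------------------------------------------------------------------
# external repacker hook (SCWRL4-compatible invocation)

def _repack_external(b: BackboneScaffold, seq: str,
                     settings: RepackSettings) -> ProteinStructure:
    with tempfile.TemporaryDirectory(prefix="rpfold-repack-") as tmp:
        tmp = Path(tmp)
        bb_path = tmp / "backbone.pdb"
        seq_path = tmp / "seq.txt"
        out_path = tmp / "out.pdb"
        renamed = BackboneScaffold(
            [Residue(r.index, seq[i],
                     [Atom(a.name, a.element, a.coords.copy())
                      for a in r.atoms])
             for i, r in enumerate(b.residues)], b.label)
        bb_path.write_text(write_structure(renamed))
        seq_path.write_text(seq.lower() + "\n")
        cmd = [settings.external_tool, "-i", str(bb_path), "-s",
               str(seq_path), "-o", str(out_path)]
        try:
            proc = subprocess.run(cmd, capture_output=True, text=True)
        except OSError as exc:
            raise ExternalToolFailure(str(exc)) from exc
        if proc.returncode != 0:
            raise ExternalToolFailure(
                f"{settings.external_tool} exited {proc.returncode}: "
                f"{proc.stderr[-500:]}")
        if not out_path.exists():
            raise ExternalToolFailure("external repacker produced no output")
        result = read_structure(out_path.read_text(), label=b.label)
        _validate_external(b, seq, result)
        return result


def _validate_external(b: BackboneScaffold, seq: str,
                       result: ProteinStructure) -> None:
    if result.sequence != seq:
        raise ExternalToolFailure("external repacker changed the sequence")
    for rb, rr in zip(b.residues, result.residues):
        for name in rotamers.BACKBONE_ATOMS:
            ab, ar = rb.atom(name), rr.atom(name)
            if ar is None or np.max(np.abs(ab.coords - ar.coords)) > 5e-3:
                raise ExternalToolFailure(
                    f"backbone moved at residue {rb.index} atom {name}")
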