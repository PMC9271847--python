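"""Native contact maps and their comparison across repacked constructs.

A contact exists between residues i and j (|j - i| >= min_sep) when any
heavy atom of i lies strictly within the cutoff (default 4.5 A) of any
heavy atom of j. Each residue pair contributes at most one contact no
matter how many atomic pairs are within range, and the contact carries the
native Calpha-Calpha distance d_ij in nm, the length unit of the
simulation model. Composite maps pool contacts over several random
permutants (per-contact occupancy counts); difference maps partition WT
vs RP contacts into common / WT-only / RP-only sets; region analytics
normalize gains and losses per named residue region.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyContactMap, IncompatibleSizes
from .structure_io import ProteinStructure

__all__ = [
    "Contact", "ContactMap", "CompositeMap", "DifferenceMap",
    "RegionGainLoss", "compute_contact_map", "composite_map",
    "difference_map", "region_gain_loss", "sensitive_regions",
    "read_contact_file", "write_contact_file",
]

ANGSTROM_TO_NM = 0.1


@dataclasses.dataclass(frozen=True, order=True)
class Contact:
    i: int          # 1-based, i < j
    j: int
    d_ij: float     # native CA-CA distance, nm

    def __post_init__(self):
        if not self.i < self.j:
            raise ValueError("contact requires i < j")
        if not self.d_ij > 0:
            raise ValueError("d_ij must be positive")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.i, self.j)


@dataclasses.dataclass
class ContactMap:
    n_residues: int
    contacts: frozenset[Contact]
    cutoff: float           # A
    min_sep: int

    @property
    def M(self) -> int:
        """Total number of contacts."""
        return len(self.contacts)

    @property
    def pairs(self) -> set[tuple[int, int]]:
        return {c.pair for c in self.contacts}

    def sorted_contacts(self) -> list[Contact]:
        return sorted(self.contacts)


@dataclasses.dataclass
class CompositeMap:
    n_residues: int
    counts: dict[tuple[int, int], int]
    n_maps: int


@dataclasses.dataclass
class DifferenceMap:
    common: set[tuple[int, int]]
    wt_only: set[tuple[int, int]]
    rp_only: set[tuple[int, int]]


@dataclasses.dataclass
class RegionGainLoss:
    """Per-region, per-RP normalized contact turnover.

    ``gained[region][k]`` / ``lost[region][k]`` are the RP-only / WT-only
    contact counts inside the region for RP k, normalized by the WT
    contact count in that region (with a floor of 1 when the region has no
    WT contacts, so gains remain reportable).
    """
    regions: dict[str, frozenset[int]]
    gained: dict[str, list[float]]
    lost: dict[str, list[float]]
    interface: str = "interface"


def compute_contact_map(s: ProteinStructure, cutoff: float = 4.5,
                        min_sep: int = 3) -> ContactMap:
    """Heavy-atom contact map at ``cutoff`` A with ``j - i >= min_sep``.

    The structure is expected to be hydrogen-free; any hydrogens present
    are ignored. Distances are compared strictly (< cutoff).
    """
    entries = s.heavy_atoms()
    ca = s.ca_coords() * ANGSTROM_TO_NM   # raises MissingCA if absent
    pts = np.array([a.coords for _, a in entries])
    res_idx = np.array([ri for ri, _ in entries])
    tree = cKDTree(pts)
    pairs: set[tuple[int, int]] = set()
    for a, b in tree.query_pairs(cutoff):
        ri, rj = int(res_idx[a]), int(res_idx[b])
        if ri > rj:
            ri, rj = rj, ri
        if rj - ri >= min_sep:
            # query_pairs uses distance <= r; enforce the strict inequality
            if np.linalg.norm(pts[a] - pts[b]) < cutoff:
                pairs.add((ri, rj))
    contacts = frozenset(
        Contact(i, j, float(np.linalg.norm(ca[i - 1] - ca[j - 1])))
        for i, j in pairs)
    return ContactMap(s.n_residues, contacts, cutoff, min_sep)


def composite_map(maps: Sequence[ContactMap]) -> CompositeMap:
    """Pool several maps; each pair's count is the number of maps it is in."""
    if not maps:
        raise IncompatibleSizes("no maps given")
    n = maps[0].n_residues
    if any(m.n_residues != n for m in maps):
        raise IncompatibleSizes("maps cover different numbers of residues")
    counts: dict[tuple[int, int], int] = {}
    for m in maps:
        for pair in m.pairs:
            counts[pair] = counts.get(pair, 0) + 1
    return CompositeMap(n, counts, len(maps))


def difference_map(wt: ContactMap, rp: ContactMap) -> DifferenceMap:
    if wt.n_residues != rp.n_residues:
        raise IncompatibleSizes("WT and RP maps cover different sizes")
    w, r = wt.pairs, rp.pairs
    return DifferenceMap(common=w & r, wt_only=w - r, rp_only=r - w)


def _contact_region(pair: tuple[int, int],
                    regions: dict[str, frozenset[int]]) -> str | None:
    """A contact belongs to a region iff both residues are inside it; a
    contact straddling two named regions goes to the interface bucket."""
    i, j = pair
    touch = [name for name, members in regions.items()
             if i in members or j in members]
    for name in touch:
        if i in regions[name] and j in regions[name]:
            return name
    if len(touch) >= 2:
        return "interface"
    return None


def region_gain_loss(wt: ContactMap, rps: Sequence[ContactMap],
                     regions: dict[str, Iterable[int]]) -> RegionGainLoss:
    """Normalized per-region contact turnover for each RP (the CORE vs
    periphery scatter analysis)."""
    reg = {name: frozenset(members) for name, members in regions.items()}
    names = list(reg) + ["interface"]
    wt_by_region = {name: 0 for name in names}
    for pair in wt.pairs:
        name = _contact_region(pair, reg)
        if name is not None:
            wt_by_region[name] += 1
    for name, cnt in wt_by_region.items():
        if name != "interface" and cnt == 0:
            warnings.warn(f"region {name!r} contains no WT contacts",
                          stacklevel=2)
    gained = {name: [] for name in names}
    lost = {name: [] for name in names}
    for rp in rps:
        diff = difference_map(wt, rp)
        g = {name: 0 for name in names}
        l = {name: 0 for name in names}
        for pair in diff.rp_only:
            name = _contact_region(pair, reg)
            if name is not None:
                g[name] += 1
        for pair in diff.wt_only:
            name = _contact_region(pair, reg)
            if name is not None:
                l[name] += 1
        for name in names:
            norm = max(1, wt_by_region[name])
            gained[name].append(g[name] / norm)
            lost[name].append(l[name] / norm)
    return RegionGainLoss(reg, gained, lost)


def sensitive_regions(composite: CompositeMap, wt: ContactMap,
                      low_occupancy: float = 0.4,
                      min_len: int = 3,
                      min_range: int = 5) -> list[tuple[int, int]]:
    """Residue windows whose packing varies across RPs.

    A contact is *variable* when its occupancy count/n_maps is at or
    below ``low_occupancy`` (WT contacts absent from every RP map enter
    at occupancy 0). Windows of length >= ``min_len`` qualify when more
    than half of the contacts touching them are variable; the purest
    windows are extracted greedily and returned as (start, end)
    inclusive 1-based segments. Short-range contacts (j - i <
    ``min_range``) are secondary-structure bookkeeping conserved across
    permutants by construction; they are left out of the census so they
    cannot mask variably packed tertiary interfaces.
    """
    if composite.n_maps < 2:
        raise ValueError("composite must pool at least 2 maps")
    # WT contacts absent from every RP map carry occupancy 0: they are
    # the strongest variability signal and must enter the census
    census = dict(composite.counts)
    for pair in wt.pairs:
        census.setdefault(pair, 0)
    entries = [((i, j), count / composite.n_maps <= low_occupancy)
               for (i, j), count in census.items() if j - i >= min_range]
    n = composite.n_residues

    # greedy extraction: repeatedly take the window with the purest
    # variability signal (fraction, then coverage, then compactness),
    # retire its contacts, and continue until nothing qualifies
    segments: list[tuple[int, int]] = []
    while True:
        best = None
        for a in range(1, n - min_len + 2):
            for b in range(a + min_len - 1, n + 1):
                tot = var = 0
                for (i, j), variable in entries:
                    if a <= i <= b or a <= j <= b:
                        tot += 1
                        if variable:
                            var += 1
                if tot == 0 or var == 0 or var / tot <= 0.5:
                    continue
                key = (var / tot, var, -(b - a), -a)
                if best is None or key > best[0]:
                    best = (key, (a, b))
        if best is None:
            break
        a, b = best[1]
        segments.append((a, b))
        entries = [e for e in entries
                   if not (a <= e[0][0] <= b or a <= e[0][1] <= b)]
    return sorted(segments)


# ---------------------------------------------------------------------------
# text interchange (whitespace-separated contact lists, # comments)

def write_contact_file(cm: ContactMap, chain: str = "A") -> str:
    lines = [f"# n_residues={cm.n_residues} cutoff={cm.cutoff} "
             f"min_sep={cm.min_sep} M={cm.M}",
             "# chain_i i chain_j j d_ij(nm)"]
    for c in cm.sorted_contacts():
        lines.append(f"{chain} {c.i} {chain} {c.j} {c.d_ij:.6f}")
    return "\n".join(lines) + "\n"


def read_contact_file(text: str) -> ContactMap:
    n_residues, cutoff, min_sep = 0, 4.5, 3
    contacts = set()
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line[1:].split():
                if "=" in tok:
                    key, _, val = tok.partition("=")
                    if key == "n_residues":
                        n_residues = int(val)
                    elif key == "cutoff":
                        cutoff = float(val)
                    elif key == "min_sep":
                        min_sep = int(val)
            continue
        _, i, _, j, d = line.split()
        contacts.add(Contact(int(i), int(j), float(d)))
    if not contacts:
        raise EmptyContactMap("no contacts in file")
    if n_residues == 0:
        n_residues = max(c.j for c in contacts)
    return ContactMap(n_residues, frozenset(contacts), cutoff, min_sep)
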