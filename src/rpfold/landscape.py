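"""Order-parameter analysis: Q, reweighted histograms, free-energy
profiles, basin/barrier/intermediate detection, and folding routes.

Q is the fraction of native contacts: a contact counts as formed in a
snapshot when its Calpha distance is strictly below 1.2 times its native
value. The free-energy profile is -ln of the Q population histogram after
single-histogram reweighting to the folding temperature, in units of
k_B T_f with the global minimum shifted to zero. Folding routes are
summarized by the per-contact formation probability C_ij averaged over
the snapshots inside a Q bin.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .contacts import ContactMap
from .dynamics import KB, Trajectory
from .errors import (AllBinsEmpty, DegenerateWeights, EmptyBin,
                     EmptyContactMap, NoTwoBasins, ZeroVariance)

__all__ = [
    "QSettings", "FreeEnergyProfile", "BasinReport", "RouteMap",
    "fraction_native_contacts", "reweight_histogram", "free_energy_profile",
    "locate_basins", "average_contact_map_at_q", "route_similarity",
]


@dataclasses.dataclass
class QSettings:
    formation_factor: float = 1.2
    n_bins: int = 50

    def __post_init__(self):
        if self.formation_factor <= 1.0:
            raise ValueError("formation factor must exceed 1")
        if self.n_bins < 10:
            raise ValueError("need at least 10 bins")

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_bins + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        e = self.bin_edges
        return 0.5 * (e[:-1] + e[1:])


@dataclasses.dataclass
class FreeEnergyProfile:
    bin_centers: np.ndarray
    dG: np.ndarray                # k_B T_f; nan where no samples
    T_f: float
    sample_counts: np.ndarray

    @property
    def occupied(self) -> np.ndarray:
        return self.sample_counts > 0

    def to_tsv(self) -> str:
        lines = ["Q\tdG_kBT\tsamples"]
        for c, g, n in zip(self.bin_centers, self.dG, self.sample_counts):
            gtxt = f"{g:.6f}" if np.isfinite(g) else "nan"
            lines.append(f"{c:.4f}\t{gtxt}\t{int(n)}")
        return "\n".join(lines) + "\n"


@dataclasses.dataclass
class BasinReport:
    q_unfolded_min: float
    q_folded_min: float
    barrier_fold: float           # k_B T_f, measured from the unfolded basin
    barrier_unfold: float
    intermediates: list[tuple[float, float]]   # (q, depth below barrier top)

    @property
    def n_intermediates(self) -> int:
        return len(self.intermediates)


@dataclasses.dataclass
class RouteMap:
    q_bin: float
    pairs: np.ndarray             # (M, 2) 1-based residue pairs
    C: np.ndarray                 # (M,) formation probabilities
    N_Q: int

    def __post_init__(self):
        assert self.N_Q >= 1
        assert np.all((self.C >= 0.0) & (self.C <= 1.0))


def fraction_native_contacts(coords: np.ndarray, cm: ContactMap,
                             qs: QSettings | None = None) -> float:
    """Q of a single Calpha snapshot (coords in nm, (N, 3))."""
    qs = qs or QSettings()
    if cm.M == 0:
        raise EmptyContactMap("contact map has no contacts")
    coords = np.asarray(coords)
    formed = 0
    for c in cm.contacts:
        r = np.linalg.norm(coords[c.j - 1] - coords[c.i - 1])
        if r < qs.formation_factor * c.d_ij:
            formed += 1
    return formed / cm.M


def reweight_histogram(q: np.ndarray, e: np.ndarray, t_sim: float,
                       t_target: float,
                       qs: QSettings | None = None) -> np.ndarray:
    """Single-histogram reweighting of the Q population to ``t_target``.

    Each sample s acquires weight exp(-(beta_target - beta_sim) E_s);
    the returned histogram is normalized to sum to 1.
    """
    qs = qs or QSettings()
    q = np.asarray(q, dtype=float)
    e = np.asarray(e, dtype=float)
    if q.size == 0:
        raise ValueError("no samples")
    if t_sim <= 0 or t_target <= 0:
        raise ValueError("temperatures must be positive")
    dbeta = 1.0 / (KB * t_target) - 1.0 / (KB * t_sim)
    logw = -dbeta * e
    logw -= logw.max()
    w = np.exp(logw)
    ess = w.sum() ** 2 / np.square(w).sum()
    if ess < 10.0:
        warnings.warn(f"effective sample size {ess:.1f} < 10",
                      DegenerateWeights, stacklevel=2)
    hist, _ = np.histogram(q, bins=qs.bin_edges, weights=w)
    total = hist.sum()
    if total <= 0:
        raise AllBinsEmpty("reweighted histogram is empty")
    return hist / total


def free_energy_profile(p_q: np.ndarray, t_f: float,
                        qs: QSettings | None = None,
                        sample_counts: np.ndarray | None = None
                        ) -> FreeEnergyProfile:
    """dG(Q) = -ln P(Q) in k_B T_f, global minimum shifted to zero.

    Empty bins are flagged as NaN, never interpolated. ``sample_counts``
    carries raw per-bin snapshot counts when known; otherwise an
    occupancy indicator is stored.
    """
    qs = qs or QSettings()
    p_q = np.asarray(p_q, dtype=float)
    occupied = p_q > 0
    if not occupied.any():
        raise AllBinsEmpty("all Q bins are empty")
    dg = np.full_like(p_q, np.nan)
    dg[occupied] = -np.log(p_q[occupied])
    dg -= np.nanmin(dg)
    if sample_counts is None:
        sample_counts = occupied.astype(int)
    return FreeEnergyProfile(qs.bin_centers, dg, t_f,
                             np.asarray(sample_counts))


def _smooth3(y: np.ndarray) -> np.ndarray:
    """3-bin moving average, edge bins averaged over available neighbors."""
    out = np.full_like(y, np.nan)
    for i in range(len(y)):
        window = y[max(0, i - 1):i + 2]
        vals = window[np.isfinite(window)]
        if vals.size:
            out[i] = vals.mean()
    return out


def locate_basins(fep: FreeEnergyProfile,
                  prominence: float = 0.5) -> BasinReport:
    """Find unfolded/folded basins, barrier heights, and intermediates.

    Works on the 3-bin smoothed profile over occupied bins. The unfolded
    basin is the lowest-Q local minimum and the folded basin the
    highest-Q one; the barrier is the maximum dG between them relative to
    each basin. Interior minima whose prominence (depth below the lower
    flanking maximum) reaches ``prominence`` k_B T_f are reported as
    intermediates.
    """
    mask = np.isfinite(fep.dG)
    qv = fep.bin_centers[mask]
    gv = _smooth3(fep.dG)[mask]
    if len(gv) < 3:
        raise NoTwoBasins("profile has too few occupied bins")
    minima = [k for k in range(len(gv))
              if (k == 0 or gv[k] <= gv[k - 1])
              and (k == len(gv) - 1 or gv[k] <= gv[k + 1])]
    # collapse plateaus
    distinct = []
    for k in minima:
        if not distinct or k - distinct[-1] > 1 or gv[k] != gv[distinct[-1]]:
            distinct.append(k)
    interior_max = None
    if len(distinct) < 2:
        raise NoTwoBasins("fewer than two local minima after smoothing")
    ku, kf = distinct[0], distinct[-1]
    seg = gv[ku:kf + 1]
    kb_top = ku + int(np.argmax(seg))
    top = gv[kb_top]
    barrier_fold = float(top - gv[ku])
    barrier_unfold = float(top - gv[kf])
    intermediates = []
    for k in distinct[1:-1]:
        left_max = gv[ku:k].max() if k > ku else top
        right_max = gv[k:kf + 1].max() if k < kf else top
        prom = min(left_max, right_max) - gv[k]
        if prom >= prominence:
            intermediates.append((float(qv[k]), float(prom)))
    return BasinReport(float(qv[ku]), float(qv[kf]), barrier_fold,
                       barrier_unfold, intermediates)


def average_contact_map_at_q(traj: Trajectory, cm: ContactMap,
                             q_bin: float,
                             qs: QSettings | None = None) -> RouteMap:
    """Per-contact formation probabilities C_ij over the snapshots whose Q
    falls in the bin containing ``q_bin``."""
    qs = qs or QSettings()
    if traj.coords is None:
        raise ValueError("trajectory was run without coordinate snapshots")
    edges = qs.bin_edges
    b = min(int(np.searchsorted(edges, q_bin, side="right")) - 1,
            qs.n_bins - 1)
    lo, hi = edges[b], edges[b + 1]
    sel = (traj.q >= lo) & (traj.q < hi if b < qs.n_bins - 1
                            else traj.q <= hi)
    if not sel.any():
        raise EmptyBin(f"no snapshots with Q in [{lo:.3f}, {hi:.3f})")
    snaps = traj.coords[sel]
    cs = cm.sorted_contacts()
    pairs = np.array([[c.i, c.j] for c in cs])
    d = np.array([c.d_ij for c in cs])
    i0 = pairs[:, 0] - 1
    j0 = pairs[:, 1] - 1
    r = np.linalg.norm(snaps[:, j0, :] - snaps[:, i0, :], axis=2)
    formed = r < qs.formation_factor * d[None, :]
    return RouteMap(float(0.5 * (lo + hi)), pairs,
                    formed.mean(axis=0), int(sel.sum()))


def route_similarity(a: RouteMap, b: RouteMap) -> float:
    """Pearson correlation of two formation-probability vectors over the
    union of their contact sets (missing contacts contribute 0)."""
    pa = {tuple(p): c for p, c in zip(a.pairs, a.C)}
    pb = {tuple(p): c for p, c in zip(b.pairs, b.C)}
    union = sorted(set(pa) | set(pb))
    va = np.array([pa.get(p, 0.0) for p in union])
    vb = np.array([pb.get(p, 0.0) for p in union])
    if np.std(va) == 0.0 or np.std(vb) == 0.0:
        raise ZeroVariance("a formation vector is constant")
    return float(np.corrcoef(va, vb)[0, 1])
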