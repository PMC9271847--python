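"""Pipeline orchestration and the three-criterion robustness verdict.

A scaffold is *robust* when, for every random permutant (RP):

1. the folded and unfolded free-energy basins sit at Q values similar to
   the wild type's (within ``basin_q_tolerance``);
2. the folding barrier is within 2 k_B T_f of the wild type's and no
   extra (or missing) folding intermediates appear;
3. the folding route correlates with the wild type's. A route change on
   its own is only annotated — it flags non-robustness when it co-occurs
   with a criterion-1 or criterion-2 failure.

The pipeline runs: permute -> repack -> contact map -> Calpha model ->
T_f search -> landscape analysis -> verdict, with the first ``n_rps``
permutants drawn with sequential seeds from a master seed (no
cherry-picking).
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import contacts as contacts_mod
from . import landscape as landscape_mod
from .contacts import ContactMap, composite_map, compute_contact_map, difference_map
from .dynamics import (SimulationSettings, TfProtocol, TransitionThresholds,
                       count_transitions, run_dynamics,
                       find_folding_temperature)
from .errors import NoImprovedRP, StageError, UnconvergedInput, ZeroVariance
from .landscape import (BasinReport, QSettings, RouteMap,
                        average_contact_map_at_q, free_energy_profile,
                        locate_basins, reweight_histogram, route_similarity)
from .repack import RepackSettings, permute_sequence, repack_side_chains
from .sbm import SBMParameters, SBMTopology, build_topology
from .structure_io import ProteinStructure, extract_backbone, strip_hydrogens

__all__ = [
    "FoldingMetrics", "RobustnessCriteria", "RobustnessReport", "RPConfig",
    "characterize_folding", "assess_robustness", "identify_rescue_contacts",
    "run_rp_pipeline",
]


@dataclasses.dataclass
class FoldingMetrics:
    label: str
    T_f: float
    q_unfolded_min: float
    q_folded_min: float
    barrier_fold: float                  # k_B T_f
    intermediates: list[tuple[float, float]]
    route: RouteMap | None
    transitions: int
    converged: bool

    def summary(self) -> dict:
        return {
            "label": self.label, "T_f": round(self.T_f, 6),
            "q_unfolded_min": round(self.q_unfolded_min, 4),
            "q_folded_min": round(self.q_folded_min, 4),
            "barrier_fold_kBTf": round(self.barrier_fold, 4),
            "n_intermediates": len(self.intermediates),
            "intermediates": [[round(q, 4), round(p, 4)]
                              for q, p in self.intermediates],
            "transitions": self.transitions,
            "converged": self.converged,
        }


@dataclasses.dataclass
class RobustnessCriteria:
    barrier_tolerance: float = 2.0       # k_B T_f
    basin_q_tolerance: float = 0.1
    route_similarity_min: float = 0.75
    n_rps: int = 5

    def __post_init__(self):
        if min(self.barrier_tolerance, self.basin_q_tolerance,
               self.route_similarity_min) <= 0 or self.n_rps < 0:
            raise ValueError("criteria must be positive (n_rps >= 0)")


@dataclasses.dataclass
class RobustnessReport:
    wt: FoldingMetrics
    rps: list[FoldingMetrics]
    verdict: str                          # robust | non_robust
    failed_criteria: dict[str, list[int]]
    route_changes: list[str]
    sensitive_regions: list[tuple[int, int]]
    rescue_contacts: list[tuple[int, int, int]]   # (i, j, occupancy)

    def to_json(self) -> str:
        payload = {
            "verdict": self.verdict,
            "wt": self.wt.summary(),
            "rps": [m.summary() for m in self.rps],
            "failed_criteria": self.failed_criteria,
            "route_changes": self.route_changes,
            "sensitive_regions": [list(seg) for seg in self.sensitive_regions],
            "rescue_contacts": [list(rc) for rc in self.rescue_contacts],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclasses.dataclass
class RPConfig:
    """Run configuration for the full pipeline.

    ``profile`` selects simulation sizes: "test" uses short runs and a
    5-transition floor suited to toy proteins on one CPU; "full" mirrors
    production conditions (15-transition floor, longer runs).
    """
    n_rps: int = 5
    master_seed: int = 0
    cutoff: float = 4.5
    min_sep: int = 3
    profile: str = "test"
    criteria: RobustnessCriteria = dataclasses.field(
        default_factory=RobustnessCriteria)
    qsettings: QSettings = dataclasses.field(
        default_factory=lambda: QSettings(n_bins=25))
    sbm_params: SBMParameters = dataclasses.field(default_factory=SBMParameters)
    repack: RepackSettings = dataclasses.field(default_factory=RepackSettings)
    run_dir: str | None = None

    def protocol(self, seed: int) -> TfProtocol:
        if self.profile == "full":
            return TfProtocol(scan_steps=2_000_000, run_steps=20_000_000,
                              min_transitions=15, seed=seed)
        # toy landscapes keep their helices formed when tertiary
        # structure melts, so the unfolded basin sits near Q ~ 0.5; the
        # hysteresis window is set just outside the two basins
        return TfProtocol(t_low=0.6, t_high=1.6, n_scan=5,
                          scan_steps=80_000, run_steps=700_000,
                          min_transitions=5, max_refine=2,
                          balance_tol=0.5,
                          thresholds=TransitionThresholds(0.4, 0.75),
                          seed=seed)


def characterize_folding(topology: SBMTopology, cm: ContactMap,
                         protocol: TfProtocol, qs: QSettings,
                         comparison_q: float | None = None
                         ) -> tuple[FoldingMetrics, float]:
    """T_f search plus landscape analysis for one construct.

    Returns the metrics and the construct's barrier-top Q (used as the
    route-comparison bin; the wild type's value is reused for its RPs when
    ``comparison_q`` is given).
    """
    t_run, diag = find_folding_temperature(topology, protocol)
    thr = protocol.thresholds
    # Production sampling close to T_f with stored coordinates. At least
    # two independent runs at the same temperature are pooled (and more
    # until enough transitions are banked); if a run never visits one
    # ensemble the temperature is nudged toward it and the pool restarted.
    prod_steps = int(1.5 * protocol.run_steps)
    pool: list = []
    ntrans = 0
    for attempt in range(8):
        settings = SimulationSettings(
            temperature=t_run, n_steps=prod_steps,
            record_stride=protocol.record_stride,
            seed=protocol.seed + 1000 + 7 * attempt, store_coords=True)
        traj = run_dynamics(topology, settings,
                            formation_factor=qs.formation_factor)
        nb = max(1, int(len(traj.q) * protocol.burn_fraction))
        pf = np.count_nonzero(traj.q[nb:] >= thr.q_folded)
        pu = np.count_nonzero(traj.q[nb:] <= thr.q_unfolded)
        if pf == 0 or pu == 0:
            t_run *= 1.05 if pu == 0 else 1.0 / 1.05
            pool = []
            continue
        pool.append((traj, nb))
        ntrans = sum(count_transitions(t.q[b:], thr) for t, b in pool)
        if len(pool) >= 2 and ntrans >= protocol.min_transitions:
            break
    if not pool:
        raise UnconvergedInput(
            f"{topology.label}: production sampling never covered both "
            f"ensembles near T={t_run:.3f}")
    q = np.concatenate([t.q[b:] for t, b in pool])
    e = np.concatenate([t.energy[b:] for t, b in pool])
    traj = dataclasses.replace(
        pool[0][0],
        steps=np.concatenate([t.steps[b:] for t, b in pool]),
        q=q, energy=e,
        coords=np.concatenate([t.coords[b:] for t, b in pool]))
    # Two-stage T_f refinement on the pooled ensemble: first balance the
    # folded/unfolded wing populations (hysteresis thresholds), then
    # locate basins on that profile and balance their local masses; the
    # final profile is built at the resulting T_f.
    from .dynamics import _reweight_balance_temperature
    from .errors import NoTwoBasins
    counts, _ = np.histogram(q, bins=qs.bin_edges)
    t_wing = _reweight_balance_temperature(q, e, t_run, thr,
                                           0.8 * t_run, 1.25 * t_run)
    t_anchor = float(t_wing) if t_wing is not None else t_run
    basins_anchor = None
    for factor in (1.0, 0.96, 1.04, 0.92, 1.08, 0.88, 1.12):
        try:
            p_try = reweight_histogram(q, e, t_run, factor * t_anchor, qs)
            basins_anchor = locate_basins(free_energy_profile(
                p_try, factor * t_anchor, qs, sample_counts=counts))
            t_anchor = factor * t_anchor
            break
        except NoTwoBasins:
            continue
    single_basin = basins_anchor is None
    if single_basin:
        # no temperature separates two basins: the construct never folds
        # completely (or never unfolds) as one cooperative unit; report
        # the lone minimum as both basins so the verdict criteria see
        # the displaced "folded" state
        p_try = reweight_histogram(q, e, t_run, t_anchor, qs)
        fep0 = free_energy_profile(p_try, t_anchor, qs,
                                   sample_counts=counts)
        occupied = np.where(np.isfinite(fep0.dG))[0]
        q0 = float(fep0.bin_centers[
            occupied[np.argmin(fep0.dG[occupied])]])
        basins_anchor = BasinReport(q0, q0, 0.0, 0.0, [])
    if single_basin:
        t_f = t_anchor
    else:
        t_f = _basin_balance_temperature(q, e, t_run, qs,
                                         basins_anchor.q_unfolded_min,
                                         basins_anchor.q_folded_min,
                                         t_center=t_anchor)
    p_q = reweight_histogram(q, e, t_run, t_f, qs)
    fep = free_energy_profile(p_q, t_f, qs, sample_counts=counts)
    if single_basin:
        basins = basins_anchor
    else:
        try:
            basins = locate_basins(fep)
        except Exception:
            basins = basins_anchor
    q_top = _barrier_top_q(fep, basins)
    route_bin = comparison_q if comparison_q is not None else q_top
    # routes use a wide window (0.1 in Q) so formation probabilities rest
    # on a meaningful number of snapshots
    route_qs = dataclasses.replace(qs, n_bins=10)
    try:
        route = average_contact_map_at_q(traj, cm, route_bin, route_qs)
    except Exception:
        route = None
    metrics = FoldingMetrics(
        label=topology.label, T_f=t_f,
        q_unfolded_min=basins.q_unfolded_min,
        q_folded_min=basins.q_folded_min,
        barrier_fold=basins.barrier_fold,
        intermediates=basins.intermediates,
        route=route, transitions=int(ntrans),
        converged=ntrans >= protocol.min_transitions)
    return metrics, q_top


def _basin_balance_temperature(q, e, t_run, qs: QSettings,
                               q_unfolded: float, q_folded: float,
                               rel_bracket: float = 0.2,
                               t_center: float | None = None) -> float:
    """Temperature at which the two basin neighborhoods (basin bin +/- 1)
    carry equal reweighted probability; bisection inside a +/-20% bracket
    around ``t_center`` (default: the sampling temperature)."""
    t_center = t_center if t_center is not None else t_run
    edges = qs.bin_edges

    def mass(p_bins, center):
        b = min(int(np.searchsorted(edges, center, side="right")) - 1,
                qs.n_bins - 1)
        lo, hi = max(0, b - 1), min(qs.n_bins, b + 2)
        return float(p_bins[lo:hi].sum())

    def gap(T):
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            p = reweight_histogram(q, e, t_run, T, qs)
        mf, mu = mass(p, q_folded), mass(p, q_unfolded)
        if mf <= 0.0:
            return -np.inf
        if mu <= 0.0:
            return np.inf
        return np.log(mf / mu)

    lo, hi = (1.0 - rel_bracket) * t_center, (1.0 + rel_bracket) * t_center
    g_lo, g_hi = gap(lo), gap(hi)
    if not (g_lo > 0 > g_hi):
        return t_center
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if gap(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _barrier_top_q(fep, basins: BasinReport) -> float:
    mask = (np.isfinite(fep.dG)
            & (fep.bin_centers >= basins.q_unfolded_min)
            & (fep.bin_centers <= basins.q_folded_min))
    if not mask.any():
        return 0.5 * (basins.q_unfolded_min + basins.q_folded_min)
    sub = np.where(mask)[0]
    return float(fep.bin_centers[sub[np.argmax(fep.dG[sub])]])


def assess_robustness(wt: FoldingMetrics, rps: list[FoldingMetrics],
                      crit: RobustnessCriteria | None = None,
                      sensitive: list[tuple[int, int]] | None = None,
                      rescue: list[tuple[int, int, int]] | None = None
                      ) -> RobustnessReport:
    """Apply the three robustness criteria to per-construct metrics."""
    crit = crit or RobustnessCriteria()
    for m in [wt] + rps:
        if not m.converged:
            raise UnconvergedInput(
                f"{m.label}: only {m.transitions} transitions")
    failed: dict[str, list[int]] = {"basins": [], "barrier": [], "route": []}
    route_changes: list[str] = []
    for k, rp in enumerate(rps, start=1):
        c1 = (abs(rp.q_unfolded_min - wt.q_unfolded_min) > crit.basin_q_tolerance
              or abs(rp.q_folded_min - wt.q_folded_min) > crit.basin_q_tolerance)
        c2 = (abs(rp.barrier_fold - wt.barrier_fold) > crit.barrier_tolerance
              or len(rp.intermediates) != len(wt.intermediates))
        route_changed = False
        if wt.route is not None and rp.route is not None:
            try:
                sim = route_similarity(wt.route, rp.route)
                route_changed = sim < crit.route_similarity_min
            except ZeroVariance:
                route_changed = False
        if c1:
            failed["basins"].append(k)
        if c2:
            failed["barrier"].append(k)
        if route_changed:
            route_changes.append(rp.label)
            if c1 or c2:
                failed["route"].append(k)
    verdict = ("robust" if not (failed["basins"] or failed["barrier"]
                                or failed["route"])
               else "non_robust")
    return RobustnessReport(wt, rps, verdict, failed, route_changes,
                            sensitive or [], rescue or [])


def identify_rescue_contacts(wt_cm: ContactMap,
                             rp_data: list[tuple[FoldingMetrics, ContactMap]],
                             region: set[int] | frozenset[int],
                             wt_barrier: float | None = None
                             ) -> list[tuple[int, int, int]]:
    """Contacts gained by the highest-barrier RP inside a sensitive region.

    A contact qualifies when it touches the region (at least one endpoint
    inside), is present in the best RP and absent from the WT. Results
    are ranked by how many RP maps contain the contact (composite
    occupancy, descending), so contacts shared across permutants rank
    first. When ``wt_barrier`` is given, at least one RP must beat it.
    """
    if not rp_data:
        raise NoImprovedRP("no RP data given")
    if (wt_barrier is not None
            and not any(m.barrier_fold > wt_barrier for m, _ in rp_data)):
        raise NoImprovedRP("no RP has a barrier above the WT's")
    return _rescue_from_best(wt_cm, rp_data, region)


def _rescue_from_best(wt_cm, rp_data, region):
    region = frozenset(region)
    best = max(rp_data, key=lambda mc: mc[0].barrier_fold)
    comp = composite_map([cm for _, cm in rp_data])
    diff = difference_map(wt_cm, best[1])
    gained = [(i, j) for (i, j) in diff.rp_only
              if i in region or j in region]
    ranked = sorted(gained, key=lambda p: (-comp.counts.get(p, 0), p))
    return [(i, j, comp.counts.get((i, j), 0)) for i, j in ranked]


def run_rp_pipeline(wt: ProteinStructure, config: RPConfig | None = None
                    ) -> RobustnessReport:
    """Full random-permutant analysis of a wild-type structure.

    Every stage error is re-raised with stage provenance. When
    ``config.run_dir`` is set, intermediate artifacts (contact maps,
    trajectories summaries, report) are written there with a manifest.
    """
    config = config or RPConfig()
    outdir = Path(config.run_dir) if config.run_dir else None
    manifest: list[str] = []

    def _write(name: str, text: str):
        if outdir is not None:
            outdir.mkdir(parents=True, exist_ok=True)
            (outdir / name).write_text(text)
            manifest.append(name)

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise StageError(name, exc) from exc

    wt = stage("strip_hydrogens", strip_hydrogens, wt)
    wt_cm = stage("wt_contacts", compute_contact_map, wt,
                  config.cutoff, config.min_sep)
    _write("wt.cmap", contacts_mod.write_contact_file(wt_cm))
    backbone = stage("extract_backbone", extract_backbone, wt)

    # build all RP structures and maps first (cheap), then simulate
    rp_maps: list[ContactMap] = []
    rp_structs: list[ProteinStructure] = []
    for k in range(1, config.criteria.n_rps + 1):
        seed = config.master_seed + k
        perm = stage(f"permute[{k}]", permute_sequence, wt.sequence, seed)
        rp = stage(f"repack[{k}]", repack_side_chains, backbone,
                   perm.permuted_sequence, config.repack)
        rp.label = f"{wt.label}-rp{k}"
        cm = stage(f"rp_contacts[{k}]", compute_contact_map, rp,
                   config.cutoff, config.min_sep)
        rp_maps.append(cm)
        rp_structs.append(rp)
        _write(f"rp{k}.cmap", contacts_mod.write_contact_file(cm))

    wt_top = stage("wt_topology", build_topology, wt, wt_cm,
                   config.sbm_params)
    wt_metrics, wt_qtop = stage(
        "wt_folding", characterize_folding, wt_top, wt_cm,
        config.protocol(config.master_seed * 101 + 11), config.qsettings)

    rp_metrics: list[FoldingMetrics] = []
    for k, (rp, cm) in enumerate(zip(rp_structs, rp_maps), start=1):
        top = stage(f"rp_topology[{k}]", build_topology, rp, cm,
                    config.sbm_params, rp.label)
        m, _ = stage(f"rp_folding[{k}]", characterize_folding, top, cm,
                     config.protocol(config.master_seed * 101 + 11 + k),
                     config.qsettings, comparison_q=wt_qtop)
        rp_metrics.append(m)

    sensitive: list[tuple[int, int]] = []
    rescue: list[tuple[int, int, int]] = []
    if rp_maps:
        comp = composite_map(rp_maps)
        sensitive = stage("sensitive_regions",
                          contacts_mod.sensitive_regions, comp, wt_cm)
        if any(m.barrier_fold > wt_metrics.barrier_fold for m in rp_metrics):
            region = (frozenset(range(1, wt.n_residues + 1))
                      if not sensitive else
                      frozenset(r for lo, hi in sensitive
                                for r in range(lo, hi + 1)))
            rescue = _rescue_from_best(
                wt_cm, list(zip(rp_metrics, rp_maps)), region)

    if not rp_metrics:
        report = RobustnessReport(wt_metrics, [], "robust",
                                  {"basins": [], "barrier": [], "route": []},
                                  [], sensitive, rescue)
    else:
        report = stage("assess", assess_robustness, wt_metrics, rp_metrics,
                       config.criteria, sensitive, rescue)
    _write("report.json", report.to_json())
    if outdir is not None:
        _write("manifest.txt", "\n".join(manifest + ["manifest.txt"]) + "\n")
    return report
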