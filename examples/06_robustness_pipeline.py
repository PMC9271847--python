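"""End-to-end scaffold-robustness assessment of a toy design.

Runs the full pipeline (permute -> repack -> contacts -> Calpha model ->
T_f search -> landscape -> three-criterion verdict) with two random
permutants to keep the example quick; the study default is five.
Takes a few minutes on one CPU.
"""
import dataclasses

from rpfold import RPConfig, RobustnessCriteria, run_rp_pipeline
from rpfold.toys import balanced_toy

wt = balanced_toy(seed=0)
config = RPConfig(master_seed=1, profile="test",
                  criteria=RobustnessCriteria(n_rps=2))
report = run_rp_pipeline(wt, config)

print(f"verdict: {report.verdict}")
print(f"WT   T_f={report.wt.T_f:.3f}  basins=({report.wt.q_unfolded_min:.2f},"
      f" {report.wt.q_folded_min:.2f})  barrier={report.wt.barrier_fold:.2f} kBTf")
for m in report.rps:
    print(f"{m.label}  T_f={m.T_f:.3f}  basins=({m.q_unfolded_min:.2f},"
          f" {m.q_folded_min:.2f})  barrier={m.barrier_fold:.2f} kBTf  "
          f"intermediates={len(m.intermediates)}")
print("failed criteria per RP:", report.failed_criteria)
print("route changes:", report.route_changes)
# "robust" requires every RP to keep basins, barrier and route close to
# the wild type's; any criterion failure flips the verdict.
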