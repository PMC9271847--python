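"""Langevin folding runs and the free-energy profile over Q.

Runs the hairpin model near its folding temperature, counts transitions,
and prints the reweighted free-energy profile -ln P(Q).
"""
import numpy as np

from rpfold import (QSettings, SimulationSettings, build_topology,
                    compute_contact_map, count_transitions,
                    free_energy_profile, reweight_histogram, run_dynamics)
from rpfold.toys import hairpin_toy

s = hairpin_toy(seed=0)
top = build_topology(s, compute_contact_map(s))

settings = SimulationSettings(temperature=1.0, n_steps=1_500_000,
                              record_stride=200, seed=11,
                              store_coords=False)
traj = run_dynamics(top, settings)
print(f"T = {settings.temperature}: <Q> = {traj.q.mean():.3f}, "
      f"{count_transitions(traj.q)} folding/unfolding transitions")

# one bin per attainable Q value (M = 11 contacts)
qs = QSettings(n_bins=11)
p_q = reweight_histogram(traj.q, traj.energy, settings.temperature,
                         settings.temperature, qs)
prof = free_energy_profile(p_q, settings.temperature, qs)
print("\nQ        dG/kBT")
for c, g in zip(prof.bin_centers, prof.dG):
    bar = "#" * int(3 * g) if np.isfinite(g) else ""
    print(f"{c:.2f}  {g if np.isfinite(g) else float('nan'):8.2f}  {bar}")
# Two low-dG basins (small and large Q) separated by a barrier indicate
# two-state folding; a dip in the barrier would be an intermediate.
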