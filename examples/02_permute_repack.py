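"""Random-permutant construction: permute a sequence, repack the backbone.

Shows that permutation conserves composition, that the backbone is
untouched, and how the contact map responds (the difference map is the
per-permutant packing perturbation).
"""
from collections import Counter

from rpfold import (compute_contact_map, difference_map, extract_backbone,
                    permute_sequence, repack_side_chains)
from rpfold.toys import balanced_toy

wt = balanced_toy(seed=0)
wt_map = compute_contact_map(wt)
backbone = extract_backbone(wt)
print(f"WT {wt.label}: {wt.n_residues} residues, M={wt_map.M}")
print(f"WT sequence:  {wt.sequence}")

for seed in (1, 2):
    rec = permute_sequence(wt.sequence, seed)
    assert Counter(rec.permuted_sequence) == Counter(wt.sequence)
    rp = repack_side_chains(backbone, rec.permuted_sequence)
    rp_map = compute_contact_map(rp)
    d = difference_map(wt_map, rp_map)
    print(f"RP{seed} sequence: {rec.permuted_sequence}")
    print(f"  M={rp_map.M}  common={len(d.common)}  "
          f"lost={len(d.wt_only)}  gained={len(d.rp_only)}")
# Common contacts are mostly backbone-driven (intra-helix, inter-strand);
# lost/gained ones trace where shuffled side-chain sizes changed packing.
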