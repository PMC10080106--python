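"""Automated hierarchical gating of a synthetic healthy donor.

Generates 100,000 PBMC events (including debris, doublets and dead cells),
applies the packaged PBMC gating tree with automatic threshold placement,
and prints the recovered subset frequencies next to the generator's ground
truth.
"""

import cytoscreen as cs

tree = cs.load_population_tree("pbmc_composition")
gating = cs.load_gating_tree("pbmc_tree")

donor = cs.DonorSpec("D1", composition_jitter=0.0, seed=1)
em = cs.generate_donor_events(tree, donor, 100_000)
result = cs.apply_gating(em, gating, seed=0)

freq = cs.subset_frequencies(result, "D1").set_index("subset")
print("auto-placed thresholds (asinh scale):")
for key, thr in sorted(result.thresholds.items()):
    print(f"  {key:30s} {thr:8.3f}")

print("\ngated percentages of viable PBMCs vs generator truth:")
truth = {"t_cells": 70.6, "b_cells": 7.5, "nk": 7.1, "mono_dc": 4.1}
for subset, expected in truth.items():
    got = freq.loc[subset, "pct_of_denominator"]
    print(f"  {subset:10s} gated {got:5.2f}%   truth {expected:5.2f}%")

print("\nB-cell subsets (% of B cells; truth: naive 59.4, UM 14.6, "
      "SwMe 18.5, DN 7.5):")
for subset in ("b_naive", "b_um", "b_swme", "b_dn"):
    print(f"  {subset:10s} {freq.loc[subset, 'pct_of_parent']:5.2f}%")
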