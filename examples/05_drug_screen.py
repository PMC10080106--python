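"""In-vitro drug screen: fractional differences, masking, tests, clustering.

Simulates 6 donors under a vehicle control and three synthetic drugs (one of
which multiplies T-cell CD25 by 1.5, implying a ground-truth fractional
difference of +50%), gates every sample, extracts per-subset activation
MFIs, and runs the screening statistics: per-donor FD vs the vehicle, the
+/-150% outlier mask, per-feature one-sample t-tests with star annotation,
and complete-linkage clustering of the drug columns.
"""

import numpy as np
import pandas as pd

import cytoscreen as cs

tree = cs.load_population_tree("pbmc_composition")
gating = cs.load_gating_tree("pbmc_tree")
drugs = {
    "drug1": cs.ConditionEffect("drug1", {("t_cells", "CD25"): 1.5}),
    "drug2": cs.ConditionEffect("drug2", {("mono_dc", "CD38"): 0.6}),
    "drug3": cs.ConditionEffect("drug3", {}),  # inert
}
subsets = ["t_cells", "b_cells", "nk", "mono_dc"]
markers = ["CD69", "CD25", "CD38", "CD95", "CD86"]

rows = []
seeds = np.random.SeedSequence(11).generate_state(24)
k = 0
for i in range(6):
    for cond in ["DMSO", *drugs]:
        t = tree if cond == "DMSO" else cs.apply_condition(tree, drugs[cond])
        donor = cs.DonorSpec(f"D{i+1}", seed=int(seeds[k]) % 2**31)
        k += 1
        em = cs.generate_donor_events(t, donor, 20_000)
        res = cs.apply_gating(em, gating, seed=0)
        mfi = cs.subset_mfi(em, res, markers, sample_id=f"D{i+1}_{cond}",
                            subsets=subsets)
        rows.append(mfi.assign(donor=f"D{i+1}", condition=cond))

result = cs.screen(pd.concat(rows))
print("mean FD matrix (fraction of vehicle; +0.5 = +50%):")
print(result.fd.masked_values().round(3).to_string())
print("\nsignificant (feature, drug) pairs:")
sig = result.tests.query("p < 0.05").sort_values("p")
print(sig[["subset", "marker", "treatment", "mean_fd", "p", "stars"]]
      .round(4).to_string(index=False))
print(f"\ndrug column order after clustering: {result.clustering.order}")
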