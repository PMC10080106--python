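"""Panel spectral compatibility: similarity matrix and complexity score.

Loads the packaged 22-colour PBMC panel, computes every pairwise similarity
index (cosine overlap of the unit-norm spectral fingerprints; 0 = unique
spectra, 1 = identical) and the panel-level complexity score (sum of all
pairwise indices).  High pairwise values flag fluorophore pairs that will be
hard to unmix.
"""

import cytoscreen as cs

panel = cs.load_panel("pbmc_panel")
sim = cs.similarity_matrix(panel)
score = cs.complexity_score(sim)

frame = sim.to_frame()
print(f"panel {panel.name!r}: {len(panel)} channels")
print(f"complexity score (sum of pairwise similarity indices): {score:.2f}")

pairs = (
    frame.where(~(frame == 1.0))
    .stack()
    .sort_values(ascending=False)
    .drop_duplicates()
    .head(5)
)
print("\nmost similar fluorophore pairs (hardest to unmix):")
for (a, b), v in pairs.items():
    print(f"  {a:>16s} vs {b:<16s} similarity {v:.3f}")
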