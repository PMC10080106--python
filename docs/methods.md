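# Methods

This note documents the models, defaults and numerical choices behind
`cytoscreen`, and what the synthetic-data validation does and does not show
about real cytometry data.

## Spectral model and unmixing

A 3-laser spectral cytometer is modelled as 38 detectors (16 violet, 14
blue, 8 red) with fixed centre wavelengths. Each fluorophore's signature is
a non-negative vector over those detectors, clipped at zero and normalised
to unit L2 norm. The packaged panels build *synthetic* signatures: per
laser, a Gaussian emission bump at the fluorophore's peak wavelength
(zeroed below the laser line) scaled by a per-laser excitation efficiency.
Real dye spectra are asymmetric with long red tails; the synthetic shapes
nevertheless reproduce the qualitative overlap structure (e.g. APC vs
AlexaFluor647 at similarity 0.995, tandem dyes distinguished mainly by
excitation pattern) and give full-rank panels (Gram condition number ≈ 7·10³
for the packaged 22-colour panels).

The similarity index is cosine similarity of unit-norm signatures and the
complexity score is the upper-triangle sum of the pairwise indices. Both are
open surrogates for trademarked, unpublished vendor indices; they share the
endpoints (0 unique / 1 identical) and the monotonicity (more pairwise
overlap ⇒ higher panel complexity) but are **not** expected to reproduce
vendor-printed complexity values, which are therefore not validation
targets.

Unmixing solves per-event ordinary least squares via the normal equations
(`a = x Sᵀ(S Sᵀ)⁻¹`), without a non-negativity constraint, matching common
spectral-unmixing practice; whether vendor software weights detectors is
unknown, so the unweighted form was chosen and a weighted variant is out of
scope. A Gram condition number above 10⁸ raises a collinearity error naming
the most similar signature pair. Reference signatures from controls are the
per-detector median of single-stain events minus the median of unstained
events (robust to carrier cells in the stain tube; invariant to common
additive background), clipped at zero and renormalised.

## Synthetic events

Marker intensities are log-normal on the raw scale per population — the
standard first-order model for cytometry fluorescence. Named levels set the
raw-scale median: neg 120, low 900, pos 5 000, high 20 000, with log-scale
σ = 0.45 throughout; bimodal markers (e.g. memory markers within a Th
subset) are log-normal mixtures. Because positivity is encoded purely in
the log-location and populations are well separated on the asinh scale
(~0.7 vs ~4.2 at cofactor 150), subset identities are crisp. Real data have
heavier tails, spillover-spreading error that widens negatives after
unmixing, autofluorescence structure, and continua between populations;
passing recovery tests here therefore demonstrates correctness of the
*pipeline logic* (thresholding, bookkeeping, statistics), not expected
accuracy on clinical samples.

Composition is a tree of fractions-of-parent. The packaged healthy-donor
fixtures encode published across-donor means (T 70.6 %, B 7.5 %, NK 7.1 %
of viable; B subsets 59.4/14.6/18.5/7.5 %; CD4⁺ 54.5 % of αβ T cells; Th
subsets 32.9/2.0/7.0/7.0/10.1/3.4 % of CD4⁺; and so on), with three reading
decisions worth noting:

- The printed classical/intermediate/non-classical monocyte percentages
  (43.5/5.4/2.1) only cohere with the printed monocyte (4.1 % of viable)
  and DC (2.1 % of viable) figures if they are fractions of the whole
  HLA-DR⁺ CD3⁻CD19⁻ compartment, whose CD14⁻CD16⁻ quadrant carries the DCs.
  The fixture uses that reading.
- The αβ T-cell subset means sum to 93.5 %; the residue is absorbed into
  the double-negative gate, leaving the CD4⁺ fraction at its printed value.
- Th17 and Treg share an identical printed mean/IQR (7.0 %, 1.2), likely a
  typographical duplication; both are kept at 7.0 %.
- CCR7/CD45RA memory states are per-population mixtures, so the
  memory-quadrant marginals are approximate rather than pinned means.

Donor variability multiplies composition log-odds by exp(N(0, σ²)) with
σ = 0.15 by default (the source material reports only that donors "differ
slightly"), then renormalises. QC classes default to 5 % debris (forward
scatter below the fixed 50 000-unit floor), 5 % doublets (pulse area ≈ 2 ×
height, so they fail the FSC-H/FSC-A ∈ [0.75, 1.30) singlet window) and
10 % dead cells (bright viability dye; ~80–90 % viability overall is
typical of stimulated PBMC cultures).

Conditions (stimulation, drugs, disease) multiply the raw-scale median of
targeted (population, marker) pairs by k > 0 — a log-location shift of
ln k — so the ground-truth fractional difference is exactly k − 1.
Composition effects override leaf fractions with a designated sibling
absorbing the balance. The stimulation preset (CD69 ×5 globally, CD25 ×2,
CD38 ×2.5, myeloid HLA-DR/CD86/CD169 up, B/NK CD27 down) and the
disease preset (activation markers up, CD45RA down, Th2 down / Tfh, Tph,
Treg up) use nominal magnitudes: the underlying study discloses effect
directions but no effect sizes, so the magnitudes are package choices,
fixed once and labelled synthetic.

The titration generator draws the positive population around a saturating
binding curve `MFI_max·c/(c + K) + bg(c)` (defaults MFI_max 20 000, K =
1 µL/test) and the negative around `bg(c) = 100 + 40·c`. The linear
background rise is an invented, synthetic-only device that makes the stain
index unimodal across the 2-fold ladder (20 → 0.3125 µL/test), emulating
over-titration spread; it is not a biophysical model.

## Automated gating

Gating runs on asinh(x/150) (scatter channels raw). Threshold placement per
gate, computed on the parent population: (1) `kde_valley` — Gaussian KDE
with Silverman bandwidth on up to 20 000 subsampled events, evaluated on a
512-point grid; the threshold is the deepest minimum between the two
highest modes; unimodal data raise a no-valley error; (2) fallback `gmm2` —
the equal-posterior boundary of a seeded 2-component Gaussian mixture;
(3) last resort, the median. Methods requiring structure need ≥ 50 events;
an empty parent yields empty descendants without error. Quadrant thresholds
are placed once per quadrant family on the shared parent, so the four
quadrants exactly partition it. The tie-break is global and tested: a value
equal to the threshold is positive.

Gates without numeric definitions in the source hierarchy are
operationalised as documented defaults: Tph "PD-1 high" is PD-1 above the
90th percentile of CXCR5⁻CD45RA⁻ CD4⁺ events (which by construction flags
~10 % of that scope — the Tph frequency is therefore upward-biased when the
true Tph fraction is below 10 %); Treg "CD127 low" is a KDE-valley split.
Th-subset gates overlap by definition and are non-exclusive overlay gates:
they contribute membership masks and statistics but not per-event labels,
which come from the exclusive spine (deepest exclusive node, later siblings
winning ties deterministically). Subsets with fewer than 20 events report
missing MFIs — medians over a handful of events are too unstable to feed
into screening statistics.

## Screening and cohort statistics

FD is stored on the fractional scale and rendered ×100. The outlier mask
removes cells with FD < −1.5 or FD > 1.5 — strict inequalities, so exactly
±150 % survives; masked cells are flagged, never zeroed, and excluded from
display and clustering but not from the donor-level t-tests. Column
clustering uses complete linkage on pairwise-complete Euclidean distance
rescaled by √(total/observed); the missing-data rule is an assumption (the
source names the heatmap tool but not its policy) and is configurable. A
column sharing no observed rows with another raises a connectivity error.

Per-feature inference is the two-sided one-sample t-test of the donor FD
replicates against 0 (df = n − 1), implemented via scipy and cross-checked
in tests against the closed-form statistic; zero-variance replicates raise
an undefined-test error rather than reporting p = 0. Stars at 0.05/0.01/
0.001 on raw p-values; no multiplicity correction by default (matching the
raw-p star convention), Benjamini–Hochberg available as an option. Cohort
tests use the pooled-variance Student's form by default with a Welch
option, since the source specifies "Student's t-test" without stating the
variance assumption.

The cohort embedding min-max normalises each feature across donors
(constant features map to 0 by convention — the 0/0 case), then removes
the ⌊0.10·F⌋ lowest-variance features (stable ties by column order) before
column-centred 3-component PCA — the documented order of operations.
Component signs are fixed by making each component's largest-magnitude
loading positive. Separation is the mean silhouette coefficient of the
group labels in PC space: an interpretable, threshold-free stand-in for
judging group separation from a 3-D PCA plot by eye.

## Validation problem sizes

The test suite and acceptance script size the simulations as follows, as
package defaults: gated-recovery cohorts use 6 donors × 100 000 events
(multinomial SE of a 70 % subset at n ≈ 80 000 viable is ~0.16 points, far
inside the ±2-point recovery tolerance); the null t-test calibration uses
10 000 features × 6 replicates (binomial SE 0.22 % at α = 5 %); drug-effect
recovery uses 10 replicate screens of 6 donors × 20 000 events; cohort
separation uses 20 seeds of 5 + 5 donors × 15 000 events with truth-label
MFI extraction (gating error is assessed separately, in the recovery and
screen tests). All generators are pure functions of (spec, seed).

## Known limitations

- The synthetic spectra, noise model and background kinetics are stylised;
  no spillover-spreading, acquisition-drift or autofluorescence-variation
  model is included, and QC-bead calibration and automated event cleanup of
  raw files are out of scope (the pipeline assumes cleaned list-mode data).
- The KDE-valley gate assumes bimodality on the parent; dim/continuous
  markers (true "smears") will fall back to mixture or quantile splits whose
  placement is less defensible — on real data such gates should be reviewed
  via the logged thresholds.
- Dimensionality-reduction visualisations (UMAP/tSNE) are deliberately not
  reimplemented; the per-event label/channel matrix is exposed for external
  embedding tools.
- FCS support covers list-mode float/integer files (3.0/3.1); analysis
  segments and dataset chaining via $NEXTDATA are not parsed.
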