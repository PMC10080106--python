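# Default healthy-donor PBMC composition among viable single cells.
# Top-level and within-compartment fractions encode reported across-donor
# means for this hierarchy:
#   T cells 70.6% and B cells 7.5% of viable PBMCs; B subsets naive 59.4%,
#   unswitched memory 14.6%, switched memory 18.5%, double-negative 7.5% of
#   B cells, plasmablasts/plasma cells 4.1% of IgD- B cells; NK 7.1% and the
#   HLA-DR+ monocyte/DC compartment 4.1% of viable; classical 43.5%,
#   intermediate 5.4% and non-classical 2.1% monocytes of that compartment,
#   whose CD14-CD16- remainder carries the DCs (2.1% of viable overall) with
#   pDC 28.6% and mDC 45.3%.
# Derived numbers used below:
#   non_tb (CD3-CD19-) = 1 - 0.706 - 0.075 = 0.219
#   mono_dc of non_tb  = 0.041 / 0.219  = 0.18722
#   nk of hladr_neg = 0.071 / (0.219 * 0.81278) = 0.39887
#   b_swme split: 18.5% of B = switched-memory quadrant, of which the
#   CD38+CD27+ plasmablast/plasma-cell sliver is 4.1% of the IgD- 26%:
#   pbpc = 0.26 * 0.041 = 0.01066, b_swme = 0.185 - 0.01066 = 0.17434.
name: pbmc_healthy
sigma: 0.45
levels: {neg: 120, low: 900, pos: 5000, high: 20000}
markers: [CD3, CD19, HLA-DR, IgD, CD27, CD38, CD56, CD16, CD14, CD11b, CD11c,
          CD69, CD25, CD95, CD86, CD126, CD169, CD70, PD-1]
populations:
  - name: t_cells
    parent: null
    fraction: 0.706
    markers:
      CD3: pos
      CD27: {mix: [[0.7, pos], [0.3, neg]]}
      CD95: low
      CD126: low

  - name: b_cells
    parent: null
    fraction: 0.075
    markers: {CD19: pos, HLA-DR: pos, CD95: low, CD126: low}
  - name: b_naive
    parent: b_cells
    fraction: 0.594
    markers: {IgD: pos, CD27: neg, CD38: low}
  - name: b_um
    parent: b_cells
    fraction: 0.146
    markers: {IgD: pos, CD27: pos, CD70: low}
  - name: b_swme
    parent: b_cells
    fraction: 0.17434
    markers: {IgD: neg, CD27: pos, CD70: low}
  - name: b_pbpc
    parent: b_cells
    fraction: 0.01066
    markers: {IgD: neg, CD27: pos, CD38: high, CD126: pos}
  - name: b_dn
    parent: b_cells
    fraction: 0.075
    markers: {IgD: neg, CD27: neg}

  - name: non_tb          # CD3- CD19- compartment
    parent: null
    fraction: 0.219
    markers: {}
  - name: mono_dc         # HLA-DR+ monocyte / dendritic-cell compartment
    parent: non_tb
    fraction: 0.18722
    markers: {HLA-DR: pos, CD11b: pos, CD11c: pos, CD86: low, CD95: low, CD126: low, PD-1: low}
  - name: mono_classical
    parent: mono_dc
    fraction: 0.435
    markers: {CD14: pos, CD16: neg, CD38: low, CD69: low}
  - name: mono_intermediate
    parent: mono_dc
    fraction: 0.054
    markers: {CD14: pos, CD16: pos, CD38: low, CD69: low}
  - name: mono_nonclassical
    parent: mono_dc
    fraction: 0.021
    markers: {CD14: neg, CD16: pos}
  - name: dc_region       # CD14- CD16- remainder of the HLA-DR+ compartment
    parent: mono_dc
    fraction: 0.490
    markers: {CD14: neg, CD16: neg}
  - name: pdc
    parent: dc_region
    fraction: 0.286
    markers: {CD11b: neg, CD11c: neg, CD70: low}
  - name: mdc
    parent: dc_region
    fraction: 0.453
    markers: {CD11b: pos, CD11c: high, CD86: low}
  - name: dc_other        # CD11b+ CD11c- residue of the DC region
    parent: dc_region
    fraction: 0.261
    markers: {CD11b: pos, CD11c: neg}

  - name: hladr_neg
    parent: non_tb
    fraction: 0.81278
    markers: {}
  - name: nk
    parent: hladr_neg
    fraction: 0.39887
    markers: {CD56: pos}
  - name: nk_early        # CD56-bright CD16- NK cells
    parent: nk
    fraction: 0.10
    markers: {CD56: high, CD16: neg, CD27: low}
  - name: nk_mature       # CD56-dim CD16+ NK cells
    parent: nk
    fraction: 0.90
    markers: {CD56: pos, CD16: pos}
  - name: other_lymphoid  # lineage-negative remainder (basophils, ILCs, ...)
    parent: hladr_neg
    fraction: 0.60113
    markers: {}
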