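# Default healthy-donor composition for the T-cell panel (viable PBMCs).
# Fractions encode reported across-donor means: CD3+ T cells 70.6% of viable;
# TCRgd 3.2% of T cells; within alpha/beta T cells CD4+ 54.5%, CD8+ 32.6%,
# double-positive 1.3% (the printed alpha/beta subset means leave 11.6%,
# absorbed into the double-negative gate); Th subsets of CD4+: Th1 32.9%,
# Th2 2.0%, Th17 7.0%, Treg 7.0%, Tfh 10.1%, Tph 3.4% — note the printed
# 7.0%/IQR 1.2 is identical for Th17 and Treg (likely a typographical
# duplication in the source; both kept at 7.0%).
# CD45RA/CCR7 memory states are encoded as per-population mixtures, so the
# memory-quadrant marginals are approximate rather than pinned means.
name: tcell_healthy
sigma: 0.45
levels: {neg: 120, low: 900, pos: 5000, high: 20000}
markers: [CD3, CD4, CD8, TCRgd, CCR7, CD45RA, CXCR3, CCR4, CCR6, CXCR5,
          PD-1, CD25, CD127, CD69, CD38, ICOS, CD134, CD71]
populations:
  - name: cd3_t
    parent: null
    fraction: 0.706
    markers: {CD3: pos, CD127: pos}
  - name: tgd
    parent: cd3_t
    fraction: 0.032
    markers: {TCRgd: pos, CD4: neg, CD8: neg,
              CD45RA: {mix: [[0.5, pos], [0.5, neg]]},
              CCR7:   {mix: [[0.3, pos], [0.7, neg]]}}
  - name: tab            # alpha/beta (TCRgd-) T cells
    parent: cd3_t
    fraction: 0.968
    markers: {TCRgd: neg}

  - name: cd4
    parent: tab
    fraction: 0.545
    markers: {CD4: pos, CD8: neg}
  - name: th1
    parent: cd4
    fraction: 0.329
    markers: {CXCR3: pos, CCR4: neg,
              CD45RA: {mix: [[0.10, pos], [0.90, neg]]},
              CCR7:   {mix: [[0.45, pos], [0.55, neg]]}}
  - name: th2
    parent: cd4
    fraction: 0.020
    markers: {CCR4: pos, CXCR3: neg,
              CD45RA: {mix: [[0.10, pos], [0.90, neg]]},
              CCR7:   {mix: [[0.60, pos], [0.40, neg]]}}
  - name: th17
    parent: cd4
    fraction: 0.070
    markers: {CCR6: pos, CCR4: neg, CXCR3: neg, CXCR5: neg,
              CD45RA: {mix: [[0.05, pos], [0.95, neg]]},
              CCR7:   {mix: [[0.50, pos], [0.50, neg]]}}
  - name: treg
    parent: cd4
    fraction: 0.070
    markers: {CD25: pos, CD127: neg,
              CD45RA: {mix: [[0.20, pos], [0.80, neg]]},
              CCR7:   {mix: [[0.60, pos], [0.40, neg]]}}
  - name: tfh
    parent: cd4
    fraction: 0.101
    markers: {CXCR5: pos, CD45RA: neg, PD-1: low, ICOS: low,
              CCR7:   {mix: [[0.60, pos], [0.40, neg]]}}
  - name: tph
    parent: cd4
    fraction: 0.034
    markers: {CXCR5: neg, CD45RA: neg, PD-1: high, ICOS: low, CD134: low,
              CCR7:   {mix: [[0.30, pos], [0.70, neg]]}}
  - name: cd4_other      # chemokine-receptor-negative CD4 cells, mostly naive
    parent: cd4
    fraction: 0.376
    markers: {CD45RA: {mix: [[0.85, pos], [0.15, neg]]},
              CCR7:   {mix: [[0.85, pos], [0.15, neg]]}}

  - name: cd8
    parent: tab
    fraction: 0.326
    markers: {CD8: pos, CD4: neg,
              CD45RA: {mix: [[0.63, pos], [0.37, neg]]},
              CCR7:   {mix: [[0.63, pos], [0.37, neg]]}}
  - name: dp             # CD4+ CD8+ double-positive
    parent: tab
    fraction: 0.013
    markers: {CD4: pos, CD8: pos,
              CD45RA: {mix: [[0.5, pos], [0.5, neg]]},
              CCR7:   {mix: [[0.5, pos], [0.5, neg]]}}
  - name: dn             # CD4- CD8- (incl. the unclassified alpha/beta rest)
    parent: tab
    fraction: 0.116
    markers: {CD4: neg, CD8: neg,
              CD45RA: {mix: [[0.5, pos], [0.5, neg]]},
              CCR7:   {mix: [[0.5, pos], [0.5, neg]]}}

  - name: non_t          # CD3- PBMCs measured alongside (B, NK, myeloid)
    parent: null
    fraction: 0.294
    markers: {CD3: neg, CD127: neg}
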