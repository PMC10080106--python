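# Rheumatoid-arthritis case preset for the T-cell composition: elevated
# activation-marker expression (CD69, CD38, ICOS, CD71 up; the naive marker
# CD45RA down) and a shifted Th landscape (Th2 down; Tfh, Tph and Treg up,
# balanced against the unpolarised CD4 remainder).  Factor magnitudes and
# composition targets are nominal synthetic choices consistent with the
# reported direction of each change.
name: ra
marker_factors:
  - {population: cd3_t, marker: CD69,   factor: 1.8}
  - {population: cd3_t, marker: CD38,   factor: 1.6}
  - {population: cd4,   marker: ICOS,   factor: 2.2}
  - {population: cd4,   marker: CD45RA, factor: 0.6}
  - {population: cd8,   marker: CD45RA, factor: 0.6}
  - {population: cd8,   marker: CD71,   factor: 1.5}
  - {population: cd4,   marker: CD134,  factor: 1.5}
composition:
  th2: 0.012
  tfh: 0.140
  tph: 0.060
  treg: 0.100
composition_balance: cd4_other
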