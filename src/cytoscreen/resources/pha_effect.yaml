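# Mitogenic (PHA) stimulation preset for the PBMC composition: a strong
# global induction of the early activation marker CD69 with broader CD25 /
# CD38 / HLA-DR / CD86 upregulation on the indicated compartments, and no
# composition change (polyclonal activation without subset-selective
# apoptosis).  The factor magnitudes are nominal synthetic choices; the
# implied ground-truth fractional difference of each pair is factor - 1.
name: pha
marker_factors:
  - {population: "*",       marker: CD69,   factor: 5.0}
  - {population: "*",       marker: CD25,   factor: 2.0}
  - {population: "*",       marker: CD38,   factor: 2.5}
  - {population: mono_dc,   marker: HLA-DR, factor: 1.6}
  - {population: mono_dc,   marker: CD86,   factor: 1.8}
  - {population: mono_dc,   marker: CD169,  factor: 2.2}
  - {population: b_cells,   marker: CD27,   factor: 0.7}
  - {population: nk,        marker: CD27,   factor: 0.7}
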