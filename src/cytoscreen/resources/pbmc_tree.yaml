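# PBMC gating hierarchy: scatter/debris -> singlets -> viable ->
# CD3/CD19 quadrants -> B subsets (IgD/CD27, plasmablasts via CD38/CD27
# within IgD-) | CD3-CD19- -> HLA-DR split -> NK (CD56, then CD16) or the
# monocyte/DC compartment (CD14/CD16 quadrants; the CD14-CD16- quadrant
# carries the DCs, split on CD11b/CD11c).
# The debris floor is a fixed forward-scatter threshold (instrument-style
# minimum FSC cutoff); every fluorescence threshold is auto-placed.
name: pbmc
cofactor: 150
denominator: viable
auto_methods: [kde_valley, gmm2]
nodes:
  - {id: cells,    parent: null,     kind: threshold, channel: FSC-A, side: "+", source: {fixed: 50000}}
  - {id: singlets, parent: cells,    kind: ratio, numerator: FSC-H, denominator: FSC-A, lo: 0.75, hi: 1.30}
  - {id: viable,   parent: singlets, kind: threshold, channel: Viability, side: "-"}

  - {id: t_cells,  parent: viable, kind: quadrant, channel_x: CD3, channel_y: CD19, quadrant: "+-"}
  - {id: b_cells,  parent: viable, kind: quadrant, channel_x: CD3, channel_y: CD19, quadrant: "-+"}
  - {id: tb_dp,    parent: viable, kind: quadrant, channel_x: CD3, channel_y: CD19, quadrant: "++"}
  - {id: non_tb,   parent: viable, kind: quadrant, channel_x: CD3, channel_y: CD19, quadrant: "--"}

  - {id: b_naive,  parent: b_cells, kind: quadrant, channel_x: IgD, channel_y: CD27, quadrant: "+-"}
  - {id: b_um,     parent: b_cells, kind: quadrant, channel_x: IgD, channel_y: CD27, quadrant: "++"}
  - {id: b_swme,   parent: b_cells, kind: quadrant, channel_x: IgD, channel_y: CD27, quadrant: "-+"}
  - {id: b_dn,     parent: b_cells, kind: quadrant, channel_x: IgD, channel_y: CD27, quadrant: "--"}
  - {id: igd_neg,  parent: b_cells, kind: boolean, expr: "b_swme | b_dn", exclusive: false}
  - {id: b_pbpc,   parent: igd_neg, kind: quadrant, channel_x: CD38, channel_y: CD27, quadrant: "++"}

  - {id: mono_dc,    parent: non_tb, kind: threshold, channel: HLA-DR, side: "+"}
  - {id: hladr_neg,  parent: non_tb, kind: threshold, channel: HLA-DR, side: "-"}
  - {id: nk,         parent: hladr_neg, kind: threshold, channel: CD56, side: "+"}
  - {id: nk_early,   parent: nk, kind: threshold, channel: CD16, side: "-"}
  - {id: nk_mature,  parent: nk, kind: threshold, channel: CD16, side: "+"}

  - {id: mono_classical,    parent: mono_dc, kind: quadrant, channel_x: CD14, channel_y: CD16, quadrant: "+-"}
  - {id: mono_intermediate, parent: mono_dc, kind: quadrant, channel_x: CD14, channel_y: CD16, quadrant: "++"}
  - {id: mono_nonclassical, parent: mono_dc, kind: quadrant, channel_x: CD14, channel_y: CD16, quadrant: "-+"}
  - {id: dc_region,         parent: mono_dc, kind: quadrant, channel_x: CD14, channel_y: CD16, quadrant: "--"}

  - {id: pdc,      parent: dc_region, kind: quadrant, channel_x: CD11b, channel_y: CD11c, quadrant: "--"}
  - {id: mdc,      parent: dc_region, kind: quadrant, channel_x: CD11b, channel_y: CD11c, quadrant: "++"}
  - {id: dc_q_bneg, parent: dc_region, kind: quadrant, channel_x: CD11b, channel_y: CD11c, quadrant: "-+"}
  - {id: dc_q_cneg, parent: dc_region, kind: quadrant, channel_x: CD11b, channel_y: CD11c, quadrant: "+-"}
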