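# T-cell gating hierarchy: scatter/debris -> singlets -> viable -> CD3+ ->
# TCRgd vs alpha/beta -> CD4/CD8/DN/DP quadrants -> CCR7/CD45RA memory
# quadrants, plus the (overlapping, non-exclusive) Th-subset gates on CD4+:
# Th1 CXCR3+CCR4-, Th2 CCR4+CXCR3-, Th17 CCR6+CCR4-CXCR3-CXCR5-,
# Treg CD25+CD127low, Tfh CXCR5+CD45RA-, Tph CXCR5-CD45RA-PD-1high (PD-1
# threshold = 90th percentile of the CXCR5- memory CD4 events).
name: tcell
cofactor: 150
denominator: viable
auto_methods: [kde_valley, gmm2]
nodes:
  - {id: cells,    parent: null,     kind: threshold, channel: FSC-A, side: "+", source: {fixed: 50000}}
  - {id: singlets, parent: cells,    kind: ratio, numerator: FSC-H, denominator: FSC-A, lo: 0.75, hi: 1.30}
  - {id: viable,   parent: singlets, kind: threshold, channel: Viability, side: "-"}

  - {id: cd3_t, parent: viable, kind: threshold, channel: CD3, side: "+"}
  - {id: tgd,   parent: cd3_t,  kind: threshold, channel: TCRgd, side: "+"}
  - {id: tab,   parent: cd3_t,  kind: threshold, channel: TCRgd, side: "-"}

  - {id: cd4, parent: tab, kind: quadrant, channel_x: CD4, channel_y: CD8, quadrant: "+-"}
  - {id: cd8, parent: tab, kind: quadrant, channel_x: CD4, channel_y: CD8, quadrant: "-+"}
  - {id: dp,  parent: tab, kind: quadrant, channel_x: CD4, channel_y: CD8, quadrant: "++"}
  - {id: dn,  parent: tab, kind: quadrant, channel_x: CD4, channel_y: CD8, quadrant: "--"}

  - {id: cd4_tn,    parent: cd4, kind: quadrant, channel_x: CCR7, channel_y: CD45RA, quadrant: "++"}
  - {id: cd4_tcm,   parent: cd4, kind: quadrant, channel_x: CCR7, channel_y: CD45RA, quadrant: "+-"}
  - {id: cd4_tem,   parent: cd4, kind: quadrant, channel_x: CCR7, channel_y: CD45RA, quadrant: "--"}
  - {id: cd4_temra, parent: cd4, kind: quadrant, channel_x: CCR7, channel_y: CD45RA, quadrant: "-+"}
  - {id: cd8_tn,    parent: cd8, kind: quadrant, channel_x: CCR7, channel_y: CD45RA, quadrant: "++"}
  - {id: cd8_tcm,   parent: cd8, kind: quadrant, channel_x: CCR7, channel_y: CD45RA, quadrant: "+-"}
  - {id: cd8_tem,   parent: cd8, kind: quadrant, channel_x: CCR7, channel_y: CD45RA, quadrant: "--"}
  - {id: cd8_temra, parent: cd8, kind: quadrant, channel_x: CCR7, channel_y: CD45RA, quadrant: "-+"}

  - id: th1
    parent: cd4
    kind: markers
    exclusive: false
    terms:
      - {channel: CXCR3, side: "+"}
      - {channel: CCR4, side: "-"}
  - id: th2
    parent: cd4
    kind: markers
    exclusive: false
    terms:
      - {channel: CCR4, side: "+"}
      - {channel: CXCR3, side: "-"}
  - id: th17
    parent: cd4
    kind: markers
    exclusive: false
    terms:
      - {channel: CCR6, side: "+"}
      - {channel: CCR4, side: "-"}
      - {channel: CXCR3, side: "-"}
      - {channel: CXCR5, side: "-"}
  - id: treg
    parent: cd4
    kind: markers
    exclusive: false
    terms:
      - {channel: CD25, side: "+"}
      - {channel: CD127, side: "-", source: {auto: kde_valley}}
  - id: tfh
    parent: cd4
    kind: markers
    exclusive: false
    terms:
      - {channel: CXCR5, side: "+"}
      - {channel: CD45RA, side: "-"}
  - id: tph
    parent: cd4
    kind: markers
    exclusive: false
    terms:
      - {channel: CXCR5, side: "-"}
      - {channel: CD45RA, side: "-"}
      - {channel: PD-1, side: "+", source: {quantile: 0.9}}
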