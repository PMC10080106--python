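# 22-colour T-cell immunophenotyping panel (3-laser V/B/R layout); same
# synthetic-signature parameterisation as the PBMC panel.
name: tcell
channels:
  - {marker: CCR7,      fluorophore: BV421,           category: maturation, concentration_ul_per_test: 1.25, emission_peak_nm: 421, width_nm: 30, excitation: {V: 1.0, B: 0.08}}
  - {marker: CD45RO,    fluorophore: Pacific Blue,    category: maturation, concentration_ul_per_test: 2.5,  emission_peak_nm: 455, width_nm: 30, excitation: {V: 1.0, B: 0.04}}
  - {marker: TCRgd,     fluorophore: BD Horizon V480, category: lineage,    concentration_ul_per_test: 2.5,  emission_peak_nm: 478, width_nm: 34, excitation: {V: 1.0, B: 0.12}}
  - {marker: Viability, fluorophore: L/D Aqua,        category: viability,  concentration_ul_per_test: 0.1,  emission_peak_nm: 526, width_nm: 40, excitation: {V: 1.0}}
  - {marker: CD8,       fluorophore: BV570,           category: lineage,    concentration_ul_per_test: 0.5,  emission_peak_nm: 570, width_nm: 30, excitation: {V: 1.0, B: 0.05}}
  - {marker: CD134,     fluorophore: BV605,           category: activation, concentration_ul_per_test: 1.25, emission_peak_nm: 605, width_nm: 38, excitation: {V: 1.0, B: 0.10}}
  - {marker: CD28,      fluorophore: BV650,           category: activation, concentration_ul_per_test: 1.25, emission_peak_nm: 645, width_nm: 30, excitation: {V: 1.0, B: 0.08}}
  - {marker: CCR6,      fluorophore: BV711,           category: lineage,    concentration_ul_per_test: 1.25, emission_peak_nm: 711, width_nm: 34, excitation: {V: 1.0, B: 0.07}}
  - {marker: CXCR5,     fluorophore: BV750,           category: lineage,    concentration_ul_per_test: 1.25, emission_peak_nm: 750, width_nm: 38, excitation: {V: 1.0, B: 0.06}}
  - {marker: PD-1,      fluorophore: BV785,           category: inhibitory, concentration_ul_per_test: 1.25, emission_peak_nm: 785, width_nm: 40, excitation: {V: 1.0, B: 0.06}}
  - {marker: CD69,      fluorophore: FITC,            category: activation, concentration_ul_per_test: 1.25, emission_peak_nm: 519, width_nm: 40, excitation: {B: 1.0, V: 0.06}}
  - {marker: CTLA-4,    fluorophore: PE,              category: inhibitory, concentration_ul_per_test: 2.5,  emission_peak_nm: 578, width_nm: 28, excitation: {B: 1.0, V: 0.25}}
  - {marker: CXCR3,     fluorophore: PE-Dazzle594,    category: lineage,    concentration_ul_per_test: 2.5,  emission_peak_nm: 610, width_nm: 30, excitation: {B: 1.0, V: 0.20}}
  - {marker: CD45RA,    fluorophore: PerCP,           category: maturation, concentration_ul_per_test: 0.5,  emission_peak_nm: 677, width_nm: 34, excitation: {B: 1.0, V: 0.03}}
  - {marker: CD71,      fluorophore: PerCP-Cy5.5,     category: activation, concentration_ul_per_test: 2.5,  emission_peak_nm: 695, width_nm: 40, excitation: {B: 1.0, V: 0.05}}
  - {marker: CCR4,      fluorophore: PerCP-eFluor710, category: lineage,    concentration_ul_per_test: 1.25, emission_peak_nm: 710, width_nm: 30, excitation: {B: 1.0, V: 0.04}}
  - {marker: CD4,       fluorophore: PE-Cy7,          category: lineage,    concentration_ul_per_test: 0.5,  emission_peak_nm: 780, width_nm: 36, excitation: {B: 1.0, V: 0.20}}
  - {marker: CD25,      fluorophore: APC,             category: activation, concentration_ul_per_test: 2.5,  emission_peak_nm: 660, width_nm: 30, excitation: {R: 1.0, B: 0.03}}
  - {marker: ICOS,      fluorophore: AlexaFluor647,   category: activation, concentration_ul_per_test: 5.0,  emission_peak_nm: 668, width_nm: 22, excitation: {R: 1.0, B: 0.04}}
  - {marker: CD127,     fluorophore: APC-R700,        category: lineage,    concentration_ul_per_test: 1.25, emission_peak_nm: 719, width_nm: 32, excitation: {R: 1.0}}
  - {marker: CD3,       fluorophore: APC-Cy7,         category: lineage,    concentration_ul_per_test: 1.25, emission_peak_nm: 780, width_nm: 36, excitation: {R: 1.0}}
  - {marker: CD38,      fluorophore: APC-Fire810,     category: activation, concentration_ul_per_test: 2.5,  emission_peak_nm: 812, width_nm: 40, excitation: {R: 1.0}}
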