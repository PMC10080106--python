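# 22-colour PBMC immunophenotyping panel for a 3-laser (V/B/R) spectral
# cytometer.  Concentrations are the titrated working amounts in µL/test.
# Emission peaks and relative laser-excitation efficiencies parameterise the
# synthetic full-spectrum signatures; widths are synthetic shape parameters,
# not measured spectra.
name: pbmc
channels:
  - {marker: CD126,     fluorophore: BV421,           category: activation, concentration_ul_per_test: 1.25, emission_peak_nm: 421, width_nm: 30, excitation: {V: 1.0, B: 0.08}}
  - {marker: HLA-DR,    fluorophore: eFluor450,       category: activation, concentration_ul_per_test: 1.25, emission_peak_nm: 450, width_nm: 32, excitation: {V: 1.0, B: 0.05}}
  - {marker: IgD,       fluorophore: BV480,           category: lineage,    concentration_ul_per_test: 0.5,  emission_peak_nm: 478, width_nm: 34, excitation: {V: 1.0, B: 0.12}}
  - {marker: Viability, fluorophore: L/D Aqua,        category: viability,  concentration_ul_per_test: 0.1,  emission_peak_nm: 526, width_nm: 40, excitation: {V: 1.0}}
  - {marker: CD16,      fluorophore: BV570,           category: lineage,    concentration_ul_per_test: 1.25, emission_peak_nm: 570, width_nm: 30, excitation: {V: 1.0, B: 0.05}}
  - {marker: IgG,       fluorophore: BV605,           category: lineage,    concentration_ul_per_test: 2.5,  emission_peak_nm: 605, width_nm: 38, excitation: {V: 1.0, B: 0.10}}
  - {marker: CD4,       fluorophore: cFluorV610,      category: lineage,    concentration_ul_per_test: 1.25, emission_peak_nm: 612, width_nm: 24, excitation: {V: 1.0, B: 0.20}}
  - {marker: CD56,      fluorophore: BV650,           category: lineage,    concentration_ul_per_test: 0.5,  emission_peak_nm: 645, width_nm: 30, excitation: {V: 1.0, B: 0.08}}
  - {marker: CD95,      fluorophore: BV711,           category: activation, concentration_ul_per_test: 1.25, emission_peak_nm: 711, width_nm: 34, excitation: {V: 1.0, B: 0.07}}
  - {marker: CD11b,     fluorophore: BV750,           category: lineage,    concentration_ul_per_test: 1.25, emission_peak_nm: 750, width_nm: 38, excitation: {V: 1.0, B: 0.06}}
  - {marker: PD-1,      fluorophore: BV785,           category: inhibitory, concentration_ul_per_test: 1.25, emission_peak_nm: 785, width_nm: 40, excitation: {V: 1.0, B: 0.06}}
  - {marker: CD11c,     fluorophore: BB515,           category: lineage,    concentration_ul_per_test: 1.25, emission_peak_nm: 515, width_nm: 24, excitation: {B: 1.0, V: 0.03}}
  - {marker: CD69,      fluorophore: FITC,            category: activation, concentration_ul_per_test: 1.25, emission_peak_nm: 519, width_nm: 40, excitation: {B: 1.0, V: 0.06}}
  - {marker: CD27,      fluorophore: PE,              category: maturation, concentration_ul_per_test: 1.25, emission_peak_nm: 578, width_nm: 28, excitation: {B: 1.0, V: 0.25}}
  - {marker: CD70,      fluorophore: PE-Dazzle594,    category: activation, concentration_ul_per_test: 5.0,  emission_peak_nm: 610, width_nm: 30, excitation: {B: 1.0, V: 0.20}}
  - {marker: CD14,      fluorophore: PerCP-Cy5.5,     category: lineage,    concentration_ul_per_test: 2.5,  emission_peak_nm: 695, width_nm: 40, excitation: {B: 1.0, V: 0.05}}
  - {marker: CD3,       fluorophore: PE-Cy7,          category: lineage,    concentration_ul_per_test: 0.5,  emission_peak_nm: 780, width_nm: 36, excitation: {B: 1.0, V: 0.20}}
  - {marker: CD25,      fluorophore: APC,             category: activation, concentration_ul_per_test: 2.5,  emission_peak_nm: 660, width_nm: 30, excitation: {R: 1.0, B: 0.03}}
  - {marker: CD169,     fluorophore: AlexaFluor647,   category: activation, concentration_ul_per_test: 2.5,  emission_peak_nm: 668, width_nm: 22, excitation: {R: 1.0, B: 0.04}}
  - {marker: CD86,      fluorophore: APC-R700,        category: activation, concentration_ul_per_test: 1.25, emission_peak_nm: 719, width_nm: 32, excitation: {R: 1.0}}
  - {marker: CD19,      fluorophore: APC-Cy7,         category: lineage,    concentration_ul_per_test: 0.5,  emission_peak_nm: 780, width_nm: 36, excitation: {R: 1.0}}
  - {marker: CD38,      fluorophore: APC-Fire810,     category: activation, concentration_ul_per_test: 2.5,  emission_peak_nm: 812, width_nm: 40, excitation: {R: 1.0}}
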