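"""Antibody titration: stain index across a 2-fold dilution ladder.

Simulates a titration series for one reagent (positive population follows a
saturating binding curve; the negative background creeps up with
concentration), computes the stain index SI = (MFI_pos - MFI_neg) /
(2 * rSD_neg) per step, and selects the working concentration as the lowest
step keeping >= 90% of the peak SI.
"""

import cytoscreen as cs

series = cs.generate_titration_series("CD28", n_events=4000, seed=42)
result = cs.titration_curve(cs.TitrationSeries.from_event_series(series))

print(result.table.round(2).to_string(index=False))
print(
    f"\nselected working concentration: {result.selected_concentration} uL/test"
    "\n(the SI rises as binding saturates, then falls as over-titration"
    "\n inflates the negative background and its robust SD)"
)
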