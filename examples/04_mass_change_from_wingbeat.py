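"""Egg-load mass change implied by the wingbeat-frequency shift.

Gravid Culex females beat their wings faster (365 vs 347 Hz on average) to
carry the extra egg mass.  Under the Deakin scaling law, wingbeat frequency
grows with body mass to the power 0.3, so the frequency shift pins down the
relative mass increase; an absolute figure additionally needs a baseline
mass, which is inferred rather than measured here.
"""

import entolidar as el

print(f"body depolarization increase: {el.percent_change(0.45, 0.62):.0f}%")
print(f"wingbeat frequency increase : {el.percent_change(347.0, 365.0):.1f}%")

est_rel = el.mass_change_from_wbf(347.0, 365.0, baseline_mass_mg=1.0, exponent=0.3)
print(f"relative mass increase      : {100 * est_rel.relative_increase:.1f}%")

baseline = el.infer_baseline_mass(0.91, 347.0, 365.0, exponent=0.3)
est = el.mass_change_from_wbf(347.0, 365.0, baseline, baseline_inferred=True)
print(f"absolute mass increase      : {est.delta_mass_mg:.2f} mg "
      f"(baseline {est.baseline_mass_mg:.2f} mg, inferred={est.baseline_inferred})")
# A fully grown Culex egg weighs 10-15 ug and clutches run 100-300 eggs, so
# a ~0.9 mg egg load is biologically plausible.
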