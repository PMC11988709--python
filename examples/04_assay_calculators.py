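"""Plate-assay calculators: alpha-amylase inhibition and Griess nitrite.

Fits a maltose standard curve from calibration wells, converts sample
absorbances to maltose equivalents, and applies the inhibition formula
100 - 100*(sample - blank)/negative_control; then quantifies nitrite by
inverting a NaNO2 standard curve fitted over 3.125-100 uM.
"""

from sgidpep import (
    InhibitionReading,
    fit_standard_curve,
    inhibition_percent,
    nitrite_concentration,
)

# maltose standards: absorbance = 0.52 * mg + 0.08 (synthetic exact line)
maltose_curve = fit_standard_curve(
    [(mg, 0.52 * mg + 0.08) for mg in (0.0, 0.25, 0.5, 1.0, 2.0)],
    concentration_unit="mg maltose",
)
print(f"maltose curve: slope {maltose_curve.slope:.3f}, "
      f"intercept {maltose_curve.intercept:.3f}, R^2 {maltose_curve.r_squared:.4f}")

blank = maltose_curve.invert(0.20)
control = maltose_curve.invert(0.75)
for absorbance in (0.30, 0.45, 0.60):
    sample = maltose_curve.invert(absorbance)
    pct = inhibition_percent(InhibitionReading(sample, blank, control))
    print(f"  sample A540={absorbance:.2f} -> {sample:.3f} mg maltose "
          f"-> {pct:.1f}% inhibition")

# Griess assay: NaNO2 standards over 3.125-100 uM
nitrite_curve = fit_standard_curve(
    [(c, 0.0081 * c + 0.045) for c in (3.125, 6.25, 12.5, 25.0, 50.0, 100.0)],
    concentration_unit="uM NaNO2",
)
for signal in (0.10, 0.50, 0.95):
    res = nitrite_concentration(signal, nitrite_curve)
    flag = " (extrapolated!)" if res.extrapolated else ""
    print(f"  Griess A540={signal:.2f} -> {res.concentration:.2f} uM nitrite{flag}")
print()
print("Less maltose released than the uninhibited control means higher")
print("inhibition; nitrite concentration is a proxy for NO production.")
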