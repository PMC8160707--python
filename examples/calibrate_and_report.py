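"""Three-point calibration to concentration units and sample reporting.

Fits the linear standards curve used for oxidative-stress assays (standards
around 30, 130 and 300 Carratelli Units), applies the inter-instrument
wavelength correction, and converts measured absorbances into
concentrations, flagging extrapolation beyond the standards span.
"""

from rawphot import (
    WavelengthCorrection,
    apply_wavelength_correction,
    fit_calibration,
    predict_concentration,
)

standards = [(0.11, 30.0), (0.46, 130.0), (1.02, 300.0)]
curve = fit_calibration(standards)
print(f"calibration: concentration = {curve.slope:.1f} * A + {curve.intercept:.1f} "
      f"{curve.unit}  (R^2 = {curve.r_squared:.5f})")

# the reading LED peaks at 522 nm vs the reference instrument's 505 nm;
# the factor is determined empirically against that reference
correction = WavelengthCorrection(factor=1.08)

print("\nsample   A(522nm)  A(corr)  concentration")
for sample_id, a in [("sample01", 0.32), ("sample02", 0.55), ("sample03", 1.20)]:
    a_corr = apply_wavelength_correction(a, correction)
    est = predict_concentration(curve, a_corr)
    flag = "  [extrapolated]" if est.extrapolated else ""
    print(f"{sample_id}   {a:7.2f}  {a_corr:7.3f}  {est.value:7.1f} {est.unit}{flag}")
print("\nvalues outside the standards span are still reported but flagged -")
print("a prompt to dilute the sample or extend the calibration.")
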