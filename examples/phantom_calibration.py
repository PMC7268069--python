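"""Build the phantom calibration line that anchors absolute quantitation.

Simulates a 1-5 mM glutathione phantom ladder, measures the edited peak area
of each series with the full pipeline, and fits area = m * conc + k.  The
slope and intercept convert in vivo areas to concentrations.
"""

import editedmrs as em

concs = [1, 2, 3, 4, 5]
series = em.simulate_phantom_series(concs, noise_sd=2.9e-6, seed=11)
cal = em.calibrate_phantom(series, concs)
print(f"calibration line: area = {cal.m:.6f} * conc + {cal.k:.2e}  "
      f"(R^2 = {cal.r_squared:.4f})")
print("slope m is the edited-peak area produced per mM of GSH; a high R^2 "
      "confirms the editing response is linear over the calibrated range")

factor = em.relaxation_factor(orientation="reciprocal")
print(f"relaxation correction factor (phantom -> in vivo): {factor:.4f}")
print(f"example: an in vivo area of 0.0029 a.u. maps to "
      f"{em.area_to_concentration(0.0029, cal, factor):.3f} mM")
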