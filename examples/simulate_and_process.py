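"""Simulate one edited MRS acquisition and walk it through preprocessing.

Builds a 20-dynamic interleaved MEGA-ON/OFF series for a 2 mM glutathione
voxel with residual water, lipid, Cr/Cho/NAA, baseline drift, phase jitter
and noise, then runs the preprocessing chain and reports what came out.
"""

import numpy as np

import editedmrs as em

series = em.simulate_mega_press(
    gsh_mm=2.0, noise_sd=2.9e-6, phase_jitter_sd=0.087,
    baseline_amplitude=2e-5, seed=7)
print(f"simulated {len(series.dynamics)} dynamics of "
      f"{series.params.n_points} points (TE {series.params.te_ms} ms, "
      f"TR {series.params.tr_ms} ms)")
print(f"ground-truth edited peak area: {series.truth['edited_area']:.3e} a.u.")

proc = em.process_series(series)
print(f"water-referencing shift applied: {proc.shift_applied_ppm:+.4f} ppm")
print(f"raw Cr-peak SNR of the averaged-OFF spectrum: {proc.raw_snr_off:.1f}")

diff = proc.difference
mask = diff.band_mask(2.6, 3.0)
peak_ppm = diff.ppm_axis[mask][np.argmax(np.real(diff.values[mask]))]
print(f"edited difference peak maximum at {peak_ppm:.3f} ppm "
      "(expected ~2.80 ppm, the closed-conformer GSH resonance)")
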