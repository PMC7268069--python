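# Methods

This note records the models, numerical choices and limitations behind
`editedmrs`, in the order the pipeline runs.

## Signal model and synthetic data

Each resonance is a one-sided damped complex exponential
`s(t) = A·exp(i(2πft + φ))·d(t)` with a Gaussian envelope
`d(t) = exp(−(t/Td)²)` by default (Lorentzian `exp(−t/Td)` available for
model-mismatch experiments). The Gaussian choice makes the absorption-mode
spectrum exactly Gaussian, so the downstream Gaussian peak model is correctly
specified; the spectral FWHM is `2√(ln 2)/(π·Td)` and the absorption-mode
spectral area on the DFT grid is `A·sw/2` regardless of `Td` — the identity
every round-trip test is built on.

Editing is phenomenological, not quantum-mechanical: the ON dynamics carry an
extra co-edited GSH component of amplitude
`gsh_mm × amplitude_per_mm × editing_efficiency` (efficiency 0.5, a typical
MEGA value; it only rescales the calibration line), the OFF dynamics carry
the same unedited content as the ON ones, and the noiseless ON − OFF
difference therefore contains exactly the edited peak(s). No multiplet
structure, chemical-shift displacement or eddy currents are simulated.
`amplitude_per_mm = 4.9e-6` puts difference-peak areas on the familiar
~2.5e-3 a.u./mM scale of edited-MRS peak-area reports.

Nuisance content: NAA (2.01 ppm), Cr (3.03), Cho (3.22) singlets; residual
water at the 4.67 ppm reference with 50× the per-mM GSH amplitude; lipid at
1.3 ppm; a broad (~90 Hz) smooth baseline hump; per-dynamic zero-order phase
jitter (SD 5°); white complex noise. Water/lipid/baseline/jitter are on by
default so the removal, referencing and autophasing stages have real work.

**Cohort generator.** Per-subject true GSH is drawn from the group × region
normal laws of the published cohort (e.g. PCC: NC 2.3674 ± 0.4049 mM,
MCI 1.7708 ± 0.3444, AD 1.7794 ± 0.4361), truncated at 0; CSF fractions are
truncated normals on [0, 0.6] with means rising NC 0.10 → MCI 0.15 → AD 0.20
(atrophy); ages and sex ratios follow the published demographics. The emitted
signal is the true concentration diluted by `(1 − V_csf)` — what PVC must
undo — and attenuated by the phantom→vivo relaxation ratio (≈ 0.789), so the
reciprocal relaxation correction is exercised genuinely. The noise default
(2.9e-6 per complex point per dynamic) is derived in closed form so a
grand-mean subject's edited peak sits at height-to-noise ≈ 5 in the processed
difference spectrum; the resulting CRLB distribution (median ≈ 6–7%) is
slightly *better* than the 10.84 ± 3.80% reported for the real cohort, i.e.
the regime is realistic rather than optimistic. What passing tests show is
therefore estimator correctness and calibration under the assumed
(Gaussian-singlet, white-noise) model — not robustness to macromolecule
baselines, frequency drift or motion, which the generator does not emulate.

## Preprocessing

Order: per-dynamic zero-order autophase (phase of the first FID point;
fallback to the first point above 1e-12 of the maximum if it is zero) →
interleaved averaging (10 ON, 10 OFF) → ON − OFF difference → HLSVD water and
lipid removal on the time-domain traces → apodization → zero-filled FFT
(default 2× to 4,096) → water referencing.

- **First-point halving.** Before the FFT the t = 0 sample is halved
  (trapezoid weighting of a one-sided signal); without it every bin carries a
  flat offset of `s[0]/2`, which biases areas by ~1%.
- **Referencing.** The shift that puts the water magnitude maximum of the
  *averaged-OFF* spectrum at 4.67 ppm is applied to all three spectra — the
  difference spectrum has no water line of its own, and the filtered spectra
  no longer do either, so the shift is measured before water removal.
- **HLSVD.** State-space Hankel-SVD on the first 512 points (L = 256), model
  order 25; poles from the shift-invariance of the leading left singular
  vectors, amplitudes from a linear solve over the full FID, dampings floored
  at 0 so no reconstructed component can grow. Only components whose
  frequency falls in the requested band are subtracted; a noiseless signal
  with nothing in-band passes through bit-exact.
- **Apodization** defaults to the identity. The NLLS fit is its own matched
  filter, and any line-broadening window correlates the bin noise: with a
  2 Hz Gaussian window the white-noise CRLB understates the Monte-Carlo area
  SD by ~2.5×. Widths are config fields for display spectra.

The wavelet raw-SNR heuristic uses a level-3 Daubechies-4 approximation of
the real spectrum (family configurable), signal = max |approximation| in the
Cr band 2.85–3.15 ppm, noise = SD of the real part over the 500 lowest-ppm
bins. It is a QC screen, not a quantitation input.

## Baseline and peak fitting

The fit alternates (a) SSA baseline estimation on (data − current peak model)
and (b) bounded least squares of the peaks on (data − baseline), until the
residual norm changes by < 0.1% or 8 outer iterations. Peak centers are
boxed to ±0.06 ppm around their priors, amplitudes ≥ 0, σ ∈ [0.5, 30] Hz;
the first pass is multi-started (3 seeded center jitters, best residual
kept).

- **Fit domain.** Default is the full complex lineshape: the spectrum of a
  one-sided Gaussian-damped resonance is `A·w(−(f−c)/(√2σ))` with `w` the
  Faddeeva function (Gaussian absorption + Dawson dispersion). Fitting real
  and imaginary parts together is the frequency-domain equivalent of a
  time-domain least squares and carries twice the information of the
  absorption part alone. `fit_domain="real"` (plain Gaussian) is available.
- **Grid decimation.** Fitting (and the CRLB) use only the original
  pre-zero-fill bins; interpolated bins add no information and their
  correlated noise would both degrade the estimate and invalidate the
  white-noise Fisher matrix.
- **SSA.** Trajectory-matrix window L = N/2 of the estimation segment
  (maximal separability: the smooth background dominates the three leading
  singular triples while narrow peaks, which need many components, are
  excluded — at L = N/8 a narrow peak leaks ~5% of its area into the
  baseline, at N/2 ~0.1%). The baseline is estimated on the fit window padded
  by ±1 ppm so the embedding scale is far coarser than a linewidth.
- **CRLB.** Fisher matrix `JᵀJ/σ²` at the optimum (stacked real/imaginary
  Jacobian in the complex domain), noise σ estimated from the signal-free
  4.0–4.4 ppm band; the area variance follows by the delta method across the
  amplitude and σ entries. Under the defaults the mean CRLB agrees with the
  Monte-Carlo SD of fitted areas to within ~8%. The QC gate rejects
  CRLB > 20% (boundary passes) or non-converged fits.
- **Fit SNR** = mean |fitted model| / SD of the real residual over the fitted
  window within 1.0–4.0 ppm. With a narrow peak in a wide window this is a
  conservative figure (a peak-height SNR of ~5 maps to a fit SNR well below
  1); it is reported for QC trend monitoring, and a zero residual returns an
  +inf sentinel with a degeneracy flag rather than an error.

## Quantitation

`conc = ((area − k)/m) × factor`. Both relaxation-factor orientations are
implemented behind an explicit setting: `as_printed` (≈ 0.789 at
TE 120/TR 2,500 with T1 397/350 ms, T2 117/95 ms) is the literal correction
expression; `reciprocal` (≈ 1.267) is the default because converting
phantom-calibrated areas to in vivo concentrations must compensate the larger
in vivo signal loss, and because published cohort area/concentration pairs
(0.0037 a.u. ↔ 2.37 mM) are consistent only with the reciprocal. Negative
concentrations (area below the intercept) are flagged, never clipped. PVC
divides by `1 − V_csf`; voxel tissue fractions come from mean GM/WM/CSF
probabilities over a mask, renormalized to sum to 1 (segmentation itself is
out of scope — the package consumes probability arrays).

## Statistics

"GLM" is a Gaussian-identity linear model (ANCOVA): mean squares and R² only
exist there. Factors are sum-to-zero coded; per-term F tests use partial
(type-III-style) sums of squares; estimated marginal means are evaluated at
the covariate mean, balanced over the other factor; pairwise contrasts carry
Bonferroni-multiplied p-values and Bonferroni-adjusted CIs (m = contrasts per
factor). Age enters as a continuous covariate (df = 1). The three-level
region factor (ACC, PCC, CINGULATE = per-subject ACC + PCC sum) is built by
`add_cingulate_rows`. Levene's test is the mean-centered variant, implemented
directly; Shapiro–Wilk, Tukey–Kramer, Kruskal–Wallis and the Pearson χ²
(no continuity correction) delegate to scipy.

ROC: AUC is the Mann–Whitney statistic with half-weight ties; the 95% CI uses
DeLong's structural-components variance; the score is negated internally when
the disease class has the lower mean, so AUC ≥ 0.5 and the Youden-optimal
cutoff stays in concentration units (reported with its direction and the J
statistic, since published "Youden index" columns sometimes print the cutoff).
Youden ties break toward higher specificity. The multivariate path fits a
maximum-likelihood logistic regression (IRLS, tol 1e-8, max 50 iterations) on
both regional concentrations plus age and sex and scores the predicted
probabilities; complete separation is detected and flagged.

## Problem sizes used in validation

The acceptance script and end-to-end tests use: a 5-point noiseless phantom
ladder; 100 seeded minimal cohorts (2 subjects/group × 2 regions, 1,200
spectra pooled) for parameter recovery; 500 noise realizations for the
CRLB/Monte-Carlo comparison; 500 null simulations for type-I calibration; and
one full-size cohort (27/19/18 subjects × 2 regions) for the group/ROC
diagnostics. These sizes put each check's sampling error well below the
tolerance it is judged at.

## Known limitations

- Phenomenological editing: no spin-system simulation, so editing efficiency
  is an input, not a prediction; GSH_ex (2.95 ppm) is an optional second peak
  without a physical conformer model.
- Singlet Gaussian fitting only — no metabolite basis sets or macromolecule
  models; real in vivo spectra with macromolecule background will show larger
  baseline–peak coupling than the synthetic tests measure.
- Zero-order phase correction only; no frequency/phase drift correction
  across dynamics, no eddy-current correction.
- The relaxation-factor orientation and the PVC direction follow internal
  consistency arguments (documented above); both remain explicit settings so
  either convention can be reproduced.
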