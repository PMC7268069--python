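"""Synthetic MEGA-PRESS data with known ground truth.

This module generates the three kinds of input the analysis consumes —
single FIDs, interleaved ON/OFF edited series, phantom calibration series and
whole NC/MCI/AD cohorts — with every latent quantity (true concentration,
CSF fraction, edited peak area) recorded, so each downstream stage can be
tested against truth without scanner data.

Signal model
------------
Each resonance is a damped complex exponential

    s_j(t) = A_j * exp(i(2*pi*f_j*t + phi_j)) * d_j(t),

where ``f_j`` is the chemical shift converted to Hz relative to the water
reference and ``d_j`` is a Gaussian ``exp(-(t/Td)^2)`` or Lorentzian
``exp(-t/Td)`` envelope.  For the Gaussian envelope the absorption-mode
(real) spectrum is exactly Gaussian, so the downstream Gaussian peak model
is well specified, and the true spectral peak area on the DFT grid is the
closed form ``A_j * spectral_width / 2`` independent of the damping.

Editing is phenomenological: peaks flagged ``editable`` receive an extra
co-edited component (amplitude proportional to concentration times the
editing efficiency) in the ON dynamics only, so the noiseless ON - OFF
difference contains the edited peaks and nothing else.  No spin-system
physics is simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .acquisition import AcquisitionParams

__all__ = [
    "PeakTruth",
    "FidDynamic",
    "RawMegaPressSeries",
    "CohortSimConfig",
    "simulate_fid",
    "simulate_mega_press",
    "simulate_phantom_series",
    "simulate_cohort",
    "default_nuisance_peaks",
    "gaussian_fwhm_hz",
    "damping_for_fwhm",
    "true_peak_area",
    "GROUPS",
    "REGIONS",
]

GROUPS = ("NC", "MCI", "AD")
REGIONS = ("ACC", "PCC")

#: a.u. of complex time-domain amplitude per mM of metabolite.  Chosen so the
#: edited difference-peak area at the default editing efficiency lands on the
#: same arbitrary-unit scale as typical edited-MRS peak-area reports
#: (~2.5e-3 a.u. per mM).
AMPLITUDE_PER_MM = 4.9e-6


def gaussian_fwhm_hz(damping_s: float) -> float:
    """Spectral FWHM (Hz) of a Gaussian time envelope exp(-(t/Td)^2).

    The continuous Fourier transform of the envelope is Gaussian with
    FWHM = 2*sqrt(ln 2) / (pi * Td).
    """
    return 2.0 * math.sqrt(math.log(2.0)) / (math.pi * damping_s)


def damping_for_fwhm(fwhm_hz: float) -> float:
    """Gaussian damping time Td (s) giving the requested spectral FWHM."""
    return 2.0 * math.sqrt(math.log(2.0)) / (math.pi * fwhm_hz)


def true_peak_area(amplitude: float, params: AcquisitionParams) -> float:
    """Closed-form absorption-mode spectral area of a Gaussian-damped peak.

    For a one-sided signal A*exp(2i*pi*f0*t)*exp(-(t/Td)^2) the real part of
    its DFT is a Gaussian whose area (amplitude x sigma x sqrt(2*pi), in
    DFT-value x Hz units) equals A * spectral_width / 2 for every Td.
    """
    return amplitude * params.spectral_width_hz / 2.0


@dataclass(frozen=True)
class PeakTruth:
    """Ground-truth description of one resonance fed to the simulator."""

    name: str
    center_ppm: float
    damping: float  # envelope time constant Td, seconds
    amplitude: float  # a.u.
    phase_rad: float = 0.0
    shape: str = "gaussian"  # or "lorentzian"
    editable: bool = False

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.damping <= 0:
            raise ValueError("damping must be > 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown lineshape {self.shape!r}")


@dataclass
class FidDynamic:
    """One complex FID of the interleaved series (condition ON or OFF)."""

    samples: np.ndarray
    condition: str  # "ON" | "OFF"
    index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.condition not in ("ON", "OFF"):
            raise ValueError("condition must be 'ON' or 'OFF'")
        if not np.all(np.isfinite(self.samples.view(float))):
            raise ValueError("FID contains non-finite samples")


@dataclass
class RawMegaPressSeries:
    """Interleaved ON/OFF FID dynamics plus acquisition metadata.

    ``truth`` carries simulator ground truth (edited amplitude and area,
    concentrations) when the series is synthetic; it is absent (None) for
    data read from disk without it.
    """

    params: AcquisitionParams
    dynamics: list[FidDynamic]
    truth: dict | None = None

    def __post_init__(self) -> None:
        n_on = sum(d.condition == "ON" for d in self.dynamics)
        n_off = len(self.dynamics) - n_on
        if n_on != n_off:
            raise ValueError("unequal counts of ON and OFF dynamics")
        for i, d in enumerate(self.dynamics):
            if len(d.samples) != self.params.n_points:
                raise ValueError("dynamic length does not match n_points")
            expected = "ON" if i % 2 == 0 else "OFF"
            if d.condition != expected:
                raise ValueError("dynamics must alternate ON/OFF starting with ON")

    def split(self) -> tuple[list[FidDynamic], list[FidDynamic]]:
        on = [d for d in self.dynamics if d.condition == "ON"]
        off = [d for d in self.dynamics if d.condition == "OFF"]
        return on, off


def _envelope(peak: PeakTruth, t: np.ndarray) -> np.ndarray:
    if peak.shape == "gaussian":
        return np.exp(-((t / peak.damping) ** 2))
    return np.exp(-t / peak.damping)


def _render_peaks(peaks: list[PeakTruth], params: AcquisitionParams,
                  t: np.ndarray, phase0_rad: float) -> np.ndarray:
    total = np.zeros(len(t), dtype=complex)
    for p in peaks:
        f = float(params.ppm_to_hz(p.center_ppm))
        total += (p.amplitude
                  * np.exp(1j * (2.0 * np.pi * f * t + p.phase_rad + phase0_rad))
                  * _envelope(p, t))
    return total


def _baseline_term(amplitude: float, params: AcquisitionParams,
                   t: np.ndarray, phase0_rad: float) -> np.ndarray:
    # broad (~90 Hz FWHM) smooth hump centred in the metabolite region;
    # fast-decaying in time so it is smooth in frequency
    if amplitude == 0.0:
        return np.zeros(len(t), dtype=complex)
    f = float(params.ppm_to_hz(3.0))
    td = 0.006
    return amplitude * np.exp(1j * (2.0 * np.pi * f * t + phase0_rad)) * np.exp(-((t / td) ** 2))


def simulate_fid(peaks: list[PeakTruth], params: AcquisitionParams,
                 noise_sd: float = 0.0, phase0_rad: float = 0.0,
                 baseline_amplitude: float = 0.0, seed: int = 0,
                 condition: str = "ON", index: int = 0) -> FidDynamic:
    """Render one FID: sum of damped resonances + smooth baseline + white noise.

    Deterministic for a fixed ``seed``.  Raises if any peak lies outside the
    sampled bandwidth or ``noise_sd`` is negative.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    lo, hi = params.ppm_span
    for p in peaks:
        if not (lo <= p.center_ppm <= hi):
            raise ValueError(f"peak {p.name!r} at {p.center_ppm} ppm is outside the "
                             f"sampled band [{lo:.2f}, {hi:.2f}] ppm")
    t = params.time_axis()
    samples = _render_peaks(peaks, params, t, phase0_rad)
    samples += _baseline_term(baseline_amplitude, params, t, phase0_rad)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        samples = samples + noise_sd * (rng.standard_normal(len(t))
                                        + 1j * rng.standard_normal(len(t)))
    return FidDynamic(samples=samples, condition=condition, index=index)


def default_nuisance_peaks(params: AcquisitionParams,
                           include_water: bool = True,
                           include_lipid: bool = True,
                           water_amplitude: float | None = None,
                           gsh_reference_amplitude: float | None = None) -> list[PeakTruth]:
    """Non-edited singlets present in both ON and OFF dynamics.

    NAA (2.01 ppm), Cr (3.03 ppm) and Cho (3.22 ppm) at amplitudes matching
    typical averaged-OFF peak-area reports; residual water at the reference
    position with 50x the edited-GSH amplitude and lipid at 1.3 ppm, both on
    by default so the water/lipid removal step has work to do.
    """
    td = damping_for_fwhm(8.0)
    peaks = [
        PeakTruth("NAA", 2.01, td, 3.2e-6),
        PeakTruth("Cr", 3.03, td, 2.8e-6),
        PeakTruth("Cho", 3.22, td, 2.6e-6),
    ]
    if include_water:
        if water_amplitude is None:
            ref = gsh_reference_amplitude if gsh_reference_amplitude is not None \
                else AMPLITUDE_PER_MM
            water_amplitude = 50.0 * ref
        peaks.append(PeakTruth("water", params.reference_ppm,
                               damping_for_fwhm(10.0), water_amplitude))
    if include_lipid:
        peaks.append(PeakTruth("lipid", 1.30, damping_for_fwhm(25.0), 4.0e-6))
    return peaks


def simulate_mega_press(gsh_mm: float,
                        nuisance: list[PeakTruth] | None = None,
                        params: AcquisitionParams | None = None,
                        editing_efficiency: float = 0.5,
                        noise_sd: float = 0.0,
                        phase0_rad: float = 0.0,
                        phase_jitter_sd: float = 0.0,
                        baseline_amplitude: float = 0.0,
                        seed: int = 0,
                        amplitude_per_mm: float = AMPLITUDE_PER_MM,
                        gsh_fwhm_hz: float = 10.0,
                        gsh_ppm: float = 2.80,
                        include_gsh_ex: bool = False,
                        frequency_offset_ppm: float = 0.0) -> RawMegaPressSeries:
    """Simulate one interleaved MEGA-ON/MEGA-OFF series.

    The unedited GSH signal (amplitude proportional to ``gsh_mm``) appears in
    both conditions and cancels in the difference; the co-edited component
    (amplitude ``gsh_mm * amplitude_per_mm * editing_efficiency``) appears in
    the ON dynamics only, so the noiseless difference holds exactly the edited
    peak(s).  ``frequency_offset_ppm`` shifts every resonance to emulate an
    instrumental frequency offset that water referencing must undo.  The
    returned series records ground truth (edited amplitude, true difference
    area) in ``.truth``.
    """
    if params is None:
        params = AcquisitionParams()
    if not (0.0 < editing_efficiency <= 1.0):
        raise ValueError("editing_efficiency must be in (0, 1]")
    if gsh_mm < 0:
        raise ValueError("gsh_mm must be >= 0")
    if params.n_dynamics % 2 != 0:
        raise ValueError("n_dynamics must be even")
    if nuisance is None:
        nuisance = default_nuisance_peaks(params)

    td = damping_for_fwhm(gsh_fwhm_hz)
    base_amp = amplitude_per_mm * gsh_mm
    edited_amp = base_amp * editing_efficiency
    unedited = [PeakTruth("GSH_unedited", gsh_ppm, td, base_amp)]
    edited = [PeakTruth("GSH_cl", gsh_ppm, td, edited_amp, editable=True)]
    if include_gsh_ex:
        edited.append(PeakTruth("GSH_ex", 2.95, td, 0.4 * edited_amp, editable=True))

    def shift(peaks: list[PeakTruth]) -> list[PeakTruth]:
        if frequency_offset_ppm == 0.0:
            return peaks
        return [replace(p, center_ppm=p.center_ppm + frequency_offset_ppm) for p in peaks]

    off_content = shift(list(nuisance) + unedited)
    on_content = shift(list(nuisance) + unedited + edited)

    rng = np.random.default_rng(seed)
    noise_seeds = rng.integers(0, 2**31 - 1, size=params.n_dynamics)
    phases = (rng.normal(0.0, phase_jitter_sd, size=params.n_dynamics)
              if phase_jitter_sd > 0 else np.zeros(params.n_dynamics))

    dynamics = []
    for i in range(params.n_dynamics):
        cond = "ON" if i % 2 == 0 else "OFF"
        content = on_content if cond == "ON" else off_content
        dynamics.append(simulate_fid(content, params, noise_sd=noise_sd,
                                     phase0_rad=phase0_rad + phases[i],
                                     baseline_amplitude=baseline_amplitude,
                                     seed=int(noise_seeds[i]),
                                     condition=cond, index=i))
    truth = {
        "gsh_mm": gsh_mm,
        "editing_efficiency": editing_efficiency,
        "amplitude_per_mm": amplitude_per_mm,
        "edited_amplitude": edited_amp,
        "edited_area": true_peak_area(edited_amp, params),
        "area_per_mm": true_peak_area(amplitude_per_mm * editing_efficiency, params),
        "gsh_ppm": gsh_ppm,
        "frequency_offset_ppm": frequency_offset_ppm,
    }
    return RawMegaPressSeries(params=params, dynamics=dynamics, truth=truth)


def simulate_phantom_series(concs_mm: list[float],
                            params: AcquisitionParams | None = None,
                            noise_sd: float = 0.0,
                            seed: int = 0,
                            **kwargs) -> list[RawMegaPressSeries]:
    """One MEGA-PRESS series per phantom concentration (identical nuisance content).

    Emulates a calibration experiment on a GSH phantom scanned at a ladder of
    known concentrations; in the noiseless limit the edited difference-peak
    area is exactly linear in concentration.
    """
    if len(concs_mm) == 0:
        raise ValueError("need at least one phantom concentration")
    if any(c < 0 for c in concs_mm):
        raise ValueError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=len(concs_mm))
    return [simulate_mega_press(c, params=params, noise_sd=noise_sd,
                                seed=int(s), **kwargs)
            for c, s in zip(concs_mm, seeds)]


def _table_like(values: dict[tuple[str, str], tuple[float, float]]) -> dict:
    return dict(values)


@dataclass
class CohortSimConfig:
    """Study conditions for a simulated NC/MCI/AD cohort.

    Group x region GSH means/SDs default to the observed cohort moments for
    absolute (relaxation-corrected) GSH concentration in ACC and PCC; CSF
    fraction distributions increase from NC to AD, reflecting atrophy, and
    are truncated to [0, 0.6].  Noise, phase jitter and baseline defaults
    put the edited peak in a realistic low-SNR regime (spectral peak SNR ~ 5
    in the difference spectrum).
    """

    gsh_mean_sd: dict = field(default_factory=lambda: {
        ("NC", "ACC"): (1.9502, 0.4223),
        ("MCI", "ACC"): (1.6224, 0.3865),
        ("AD", "ACC"): (1.5624, 0.3407),
        ("NC", "PCC"): (2.3674, 0.4049),
        ("MCI", "PCC"): (1.7708, 0.3444),
        ("AD", "PCC"): (1.7794, 0.4361),
    })
    vcsf_mean_sd: dict = field(default_factory=lambda: {
        "NC": (0.10, 0.05), "MCI": (0.15, 0.06), "AD": (0.20, 0.07),
    })
    age_mean_sd: dict = field(default_factory=lambda: {
        "NC": (68.44, 7.07), "MCI": (70.84, 7.74), "AD": (70.74, 8.33),
    })
    male_fraction: dict = field(default_factory=lambda: {
        "NC": 16 / 27, "MCI": 16 / 19, "AD": 10 / 18,
    })
    n_subjects: dict = field(default_factory=lambda: {"NC": 27, "MCI": 19, "AD": 18})
    #: complex time-domain noise SD per dynamic, set so the edited GSH peak of
    #: a grand-mean subject (~1.9 mM, mean CSF dilution, relaxation-attenuated)
    #: sits at height-to-noise ratio 5 in the processed difference spectrum:
    #: height = 1.9*0.86*0.789*amp_per_mm*eff*(sqrt(pi)*Td/2)*sw ~ 2.97e-4 and
    #: spectral noise = noise_sd*sqrt(2*n_points/n_avg) ~ 20.2*noise_sd —
    #: the low-SNR regime edited GSH detection works in
    noise_sd: float = 2.9e-6
    phase_jitter_sd: float = math.radians(5.0)
    baseline_amplitude: float = 2.0e-5
    editing_efficiency: float = 0.5
    vcsf_bounds: tuple[float, float] = (0.0, 0.6)
    #: net in vivo signal per mM relative to the calibration phantom, from the
    #: different T1 saturation and T2 decay of the two preparations; None means
    #: "compute from the default relaxation constants" (~0.789 at TE 120 ms /
    #: TR 2,500 ms).  The quantitation step undoes it with the reciprocal
    #: relaxation factor.
    relaxation_attenuation: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for key, (_, sd) in self.gsh_mean_sd.items():
            g, r = key
            if g not in GROUPS or r not in REGIONS:
                raise ValueError(f"unknown group/region {key}")
            if sd < 0:
                raise ValueError("SDs must be >= 0")
        for g, n in self.n_subjects.items():
            if n < 2:
                raise ValueError("n_subjects must be >= 2 per group "
                                 "(between/within variance undefined otherwise)")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    """Rejection-sampled truncated normal (cheap at these acceptance rates)."""
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 8)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(keep), size - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


def simulate_cohort(config: CohortSimConfig,
                    params: AcquisitionParams | None = None,
                    generate_series: bool = True
                    ) -> tuple[pd.DataFrame, dict[tuple[str, str], RawMegaPressSeries]]:
    """Draw a cohort and (optionally) its MEGA-PRESS series.

    Per-subject true GSH is drawn from the group/region normal law truncated
    at zero; the emitted series carry the tissue-diluted signal, i.e. the
    generated edited area is proportional to ``true_gsh * (1 - Vcsf)``, which
    is what partial-volume correction must undo.  Returns the latent truth
    table and a dict of series keyed by (subject_id, region).  Deterministic
    for a fixed ``config.seed``.
    """
    if params is None:
        params = AcquisitionParams()
    attenuation = config.relaxation_attenuation
    if attenuation is None:
        from .quantify import relaxation_factor
        attenuation = relaxation_factor(params, orientation="as_printed")
    rng = np.random.default_rng(config.seed)
    lo_v, hi_v = config.vcsf_bounds

    rows = []
    series: dict[tuple[str, str], RawMegaPressSeries] = {}
    for group in GROUPS:
        n = config.n_subjects.get(group, 0)
        ages = rng.normal(*config.age_mean_sd[group], size=n).clip(55, None)
        males = rng.random(n) < config.male_fraction[group]
        vcsf = _truncated_normal(rng, *config.vcsf_mean_sd[group], lo_v, hi_v, n)
        per_region_truth = {
            region: _truncated_normal(rng, *config.gsh_mean_sd[(group, region)],
                                      0.0, np.inf, n)
            for region in REGIONS
        }
        sub_seeds = rng.integers(0, 2**31 - 1, size=(n, len(REGIONS)))
        for i in range(n):
            subject_id = f"{group}{i + 1:03d}"
            for j, region in enumerate(REGIONS):
                true_gsh = float(per_region_truth[region][i])
                s = int(sub_seeds[i, j])
                rows.append({
                    "subject_id": subject_id, "group": group, "region": region,
                    "age": float(ages[i]), "sex": "M" if males[i] else "F",
                    "true_gsh_mm": true_gsh, "vcsf": float(vcsf[i]), "seed": s,
                })
                if generate_series:
                    diluted = true_gsh * (1.0 - vcsf[i])
                    series[(subject_id, region)] = simulate_mega_press(
                        diluted, params=params,
                        amplitude_per_mm=AMPLITUDE_PER_MM * attenuation,
                        editing_efficiency=config.editing_efficiency,
                        noise_sd=config.noise_sd,
                        phase_jitter_sd=config.phase_jitter_sd,
                        baseline_amplitude=config.baseline_amplitude,
                        seed=s)
    truth = pd.DataFrame(rows)
    return truth, series
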