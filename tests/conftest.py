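import numpy as np
import pytest

import editedmrs as em


@pytest.fixture(scope="session")
def params():
    return em.AcquisitionParams()


@pytest.fixture(scope="session")
def noiseless_series():
    return em.simulate_mega_press(2.0, seed=1)


@pytest.fixture(scope="session")
def noiseless_difference(noiseless_series):
    return em.process_series(noiseless_series, compute_snr=False).difference


@pytest.fixture(scope="session")
def calibration():
    series = em.simulate_phantom_series([1, 2, 3, 4, 5])
    return em.calibrate_phantom(series, [1, 2, 3, 4, 5])


def make_gaussian_spectrum(peaks, params, n=2048, noise_sd=0.0, seed=0):
    """Directly construct a frequency-domain spectrum from (A, ppm, sigma_hz) triples.

    Bypasses the FID simulator so fitting tests control the lineshape exactly.
    """
    freqs = np.linspace(params.spectral_width_hz / 2, -params.spectral_width_hz / 2,
                        n, endpoint=False)
    ppm = params.hz_to_ppm(freqs)
    vals = np.zeros(n)
    for a, c_ppm, s in peaks:
        c = params.ppm_to_hz(c_ppm)
        vals = vals + a * np.exp(-((freqs - c) ** 2) / (2 * s * s))
    if noise_sd > 0:
        vals = vals + np.random.default_rng(seed).normal(0, noise_sd, n)
    return em.Spectrum(vals.astype(complex), ppm, params)
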