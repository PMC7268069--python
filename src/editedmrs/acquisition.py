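"""Acquisition metadata for edited (MEGA-PRESS) single-voxel MRS.

The pipeline carries one :class:`AcquisitionParams` object from simulation
through processing and quantitation; every frequency/ppm conversion goes
through the helpers here so the ppm convention (water referenced at 4.67 ppm,
higher ppm = higher frequency) is defined in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np


@dataclass(frozen=True)
class AcquisitionParams:
    """Sequence and sampling parameters of one MEGA-PRESS acquisition.

    Defaults follow a 3 T protocol: TE = 120 ms, TR = 2,500 ms, 2,048 complex
    points, 20 interleaved dynamics of 16 averages, editing pulse ON at
    4.40 ppm and OFF at 5.00 ppm, water referenced at 4.67 ppm.  Spectral
    width and transmitter frequency are not part of the protocol description
    and default to 2,000 Hz and 127.73 MHz (3 T proton).
    """

    te_ms: float = 120.0
    tr_ms: float = 2500.0
    n_points: int = 2048
    spectral_width_hz: float = 2000.0
    transmitter_mhz: float = 127.73
    edit_on_ppm: float = 4.40
    edit_off_ppm: float = 5.00
    n_dynamics: int = 20
    nsa_per_dynamic: int = 16
    reference_ppm: float = 4.67

    def __post_init__(self) -> None:
        if self.te_ms <= 0:
            raise ValueError("te_ms must be positive")
        if self.tr_ms <= self.te_ms:
            raise ValueError("tr_ms must exceed te_ms")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.spectral_width_hz <= 0:
            raise ValueError("spectral_width_hz must be positive")
        if self.n_dynamics % 2 != 0:
            raise ValueError("n_dynamics must be even (interleaved ON/OFF)")
        if self.edit_on_ppm == self.edit_off_ppm:
            raise ValueError("edit_on_ppm must differ from edit_off_ppm")

    @property
    def dwell_time_s(self) -> float:
        return 1.0 / self.spectral_width_hz

    def time_axis(self, n: int | None = None) -> np.ndarray:
        """Sampling times (s) of the FID, starting at t = 0."""
        if n is None:
            n = self.n_points
        return np.arange(n) * self.dwell_time_s

    def ppm_to_hz(self, ppm: float | np.ndarray) -> float | np.ndarray:
        """Offset frequency (Hz) of a chemical shift relative to the water reference."""
        return (np.asarray(ppm) - self.reference_ppm) * self.transmitter_mhz

    def hz_to_ppm(self, hz: float | np.ndarray) -> float | np.ndarray:
        return np.asarray(hz) / self.transmitter_mhz + self.reference_ppm

    @property
    def ppm_span(self) -> tuple[float, float]:
        """(low, high) chemical-shift bounds covered by the sampling bandwidth."""
        half = self.spectral_width_hz / 2.0
        return (float(self.hz_to_ppm(-half)), float(self.hz_to_ppm(half)))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionParams":
        return cls(**d)
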