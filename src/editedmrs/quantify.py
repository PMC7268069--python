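"""Absolute quantitation of edited GSH peak areas.

Peak areas (a.u.) become millimolar concentrations through an external
phantom calibration line (area = m * conc + k), a T1/T2 relaxation
correction transferring the phantom calibration to in vivo relaxation
conditions, and a CSF partial-volume correction 1 / (1 - Vcsf), since CSF
carries a negligible amount of glutathione.

The relaxation factor is exposed in both orientations.  Written literally,
the correction multiplies by

    [1 - exp(-TR/T1_phantom)] / [1 - exp(-TR/T1_vivo)]
      * exp(-TE/T2_phantom) / exp(-TE/T2_vivo)   (~0.789 at TE 120/TR 2500),

but converting phantom-calibrated areas to in vivo concentrations requires
compensating the *larger* in vivo signal loss, i.e. the reciprocal (~1.267);
published cohort area/concentration pairs are consistent only with the
reciprocal, which is therefore the default.  The choice is an explicit,
required-to-be-deliberate setting, not a hidden convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionParams

__all__ = [
    "CalibrationCurve",
    "RelaxationConstants",
    "VoxelComposition",
    "fit_calibration",
    "relaxation_factor",
    "area_to_concentration",
    "apply_pvc",
    "tissue_fractions",
    "PAPER_CALIBRATION",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Slope, intercept and R^2 of the phantom area-vs-concentration line."""

    m: float  # a.u. per mM
    k: float  # a.u.
    r_squared: float

    def __post_init__(self) -> None:
        if self.m == 0:
            raise ValueError("calibration slope must be nonzero")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")


#: Published calibration constants for the 1-5 mM GSH phantom experiment.
PAPER_CALIBRATION = CalibrationCurve(m=0.00245, k=-0.00091, r_squared=0.994)


@dataclass(frozen=True)
class RelaxationConstants:
    """T1/T2 of GSH in vivo and in the calibration phantom (ms), 3 T literature values."""

    t1_vivo_ms: float = 397.0
    t1_phantom_ms: float = 350.0
    t2_vivo_ms: float = 117.0
    t2_phantom_ms: float = 95.0

    def __post_init__(self) -> None:
        if min(self.t1_vivo_ms, self.t1_phantom_ms,
               self.t2_vivo_ms, self.t2_phantom_ms) <= 0:
            raise ValueError("relaxation times must be positive")


@dataclass(frozen=True)
class VoxelComposition:
    """Grey-matter / white-matter / CSF volume fractions of one MRS voxel."""

    f_gm: float
    f_wm: float
    f_csf: float

    def __post_init__(self) -> None:
        for f in (self.f_gm, self.f_wm, self.f_csf):
            if not (0.0 <= f <= 1.0):
                raise ValueError("tissue fractions must lie in [0, 1]")
        if abs(self.f_gm + self.f_wm + self.f_csf - 1.0) > 1e-6:
            raise ValueError("tissue fractions must sum to 1")


def fit_calibration(concs_mm, areas) -> CalibrationCurve:
    """Ordinary least-squares line area = m * conc + k with its R^2."""
    c = np.asarray(concs_mm, dtype=float)
    a = np.asarray(areas, dtype=float)
    if len(c) != len(a):
        raise ValueError("concs and areas must have equal length")
    if len(np.unique(c)) < 3:
        raise ValueError("calibration needs >= 3 distinct concentrations")
    m, k = np.polyfit(c, a, 1)
    pred = m * c + k
    ss_res = float(np.sum((a - pred) ** 2))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationCurve(m=float(m), k=float(k), r_squared=min(max(r2, 0.0), 1.0))


def relaxation_factor(params: AcquisitionParams | None = None,
                      constants: RelaxationConstants | None = None,
                      orientation: str = "reciprocal") -> float:
    """T1/T2 saturation-and-decay correction between phantom and in vivo.

    orientation='as_printed' returns
    [1-exp(-TR/T1_p)]/[1-exp(-TR/T1_v)] * exp(-TE/T2_p)/exp(-TE/T2_v);
    orientation='reciprocal' its inverse (the default used for quantitation,
    see module docstring).  Always positive.
    """
    if params is None:
        params = AcquisitionParams()
    if constants is None:
        constants = RelaxationConstants()
    tr, te = params.tr_ms, params.te_ms
    sat = (1.0 - math.exp(-tr / constants.t1_phantom_ms)) \
        / (1.0 - math.exp(-tr / constants.t1_vivo_ms))
    decay = math.exp(-te / constants.t2_phantom_ms) \
        / math.exp(-te / constants.t2_vivo_ms)
    factor = sat * decay
    if orientation == "as_printed":
        return factor
    if orientation == "reciprocal":
        return 1.0 / factor
    raise ValueError("orientation must be 'as_printed' or 'reciprocal'")


def area_to_concentration(area: float, curve: CalibrationCurve,
                          factor: float = 1.0) -> float:
    """Invert the calibration line and apply the relaxation factor.

    concentration = ((area - k) / m) * factor, in mM.  Negative results (area
    below the intercept) are returned as-is so callers can flag rather than
    silently truncate them.
    """
    return (area - curve.k) / curve.m * factor


def apply_pvc(absolute_mm: float, comp: VoxelComposition | float) -> float:
    """CSF partial-volume correction: divide by the tissue fraction 1 - Vcsf."""
    f_csf = comp.f_csf if isinstance(comp, VoxelComposition) else float(comp)
    if f_csf >= 1.0:
        raise ValueError("voxel contains no tissue (f_csf >= 1)")
    if f_csf < 0.0:
        raise ValueError("f_csf must be >= 0")
    return absolute_mm / (1.0 - f_csf)


def tissue_fractions(mask, gm_map, wm_map, csf_map) -> VoxelComposition:
    """Mean tissue probabilities over the masked voxels, renormalized to sum to 1."""
    mask = np.asarray(mask, dtype=bool)
    maps = [np.asarray(m, dtype=float) for m in (gm_map, wm_map, csf_map)]
    for m in maps:
        if m.shape != mask.shape:
            raise ValueError("tissue maps and mask must be congruent")
        if m.min() < 0 or m.max() > 1:
            raise ValueError("tissue probabilities must lie in [0, 1]")
    if not mask.any():
        raise ValueError("empty voxel mask")
    means = np.array([m[mask].mean() for m in maps])
    total = means.sum()
    if total == 0:
        raise ValueError("all tissue probabilities are zero inside the mask")
    f = means / total
    return VoxelComposition(f_gm=float(f[0]), f_wm=float(f[1]), f_csf=float(f[2]))
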