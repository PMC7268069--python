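"""Plain-text containers for FID series, spectra and subject tables.

One acquisition is a directory holding ``metadata.json`` (all acquisition
parameters plus the per-dynamic condition order and any simulator ground
truth) and one CSV per dynamic with columns index, real, imag.  Floats are
written with 17 significant digits so a write/read round trip is exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .acquisition import AcquisitionParams
from .processing import Spectrum
from .simulate import FidDynamic, RawMegaPressSeries

__all__ = [
    "write_series", "read_series",
    "write_spectrum", "read_spectrum",
    "write_truth_table", "read_truth_table",
]

_FMT = "%.17g"


def write_series(directory, series: RawMegaPressSeries) -> Path:
    """Write one acquisition directory (metadata.json + per-dynamic CSVs)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "params": series.params.to_dict(),
        "conditions": [dyn.condition for dyn in series.dynamics],
        "truth": series.truth,
    }
    (d / "metadata.json").write_text(json.dumps(meta, indent=1))
    for i, dyn in enumerate(series.dynamics):
        arr = np.column_stack([np.arange(len(dyn.samples)),
                               dyn.samples.real, dyn.samples.imag])
        np.savetxt(d / f"dynamic_{i:03d}.csv", arr, delimiter=",",
                   header="index,real,imag", comments="", fmt=("%d", _FMT, _FMT))
    return d


def read_series(directory) -> RawMegaPressSeries:
    d = Path(directory)
    meta = json.loads((d / "metadata.json").read_text())
    params = AcquisitionParams.from_dict(meta["params"])
    dynamics = []
    for i, cond in enumerate(meta["conditions"]):
        arr = np.loadtxt(d / f"dynamic_{i:03d}.csv", delimiter=",", skiprows=1)
        dynamics.append(FidDynamic(arr[:, 1] + 1j * arr[:, 2], cond, i))
    return RawMegaPressSeries(params=params, dynamics=dynamics,
                              truth=meta.get("truth"))


def write_spectrum(path, spectrum: Spectrum, provenance: dict | None = None) -> Path:
    """CSV (ppm, real, imag); optional JSON provenance sidecar next to it."""
    path = Path(path)
    arr = np.column_stack([spectrum.ppm_axis,
                           spectrum.values.real, spectrum.values.imag])
    np.savetxt(path, arr, delimiter=",", header="ppm,real,imag", comments="",
               fmt=_FMT)
    if provenance is not None:
        sidecar = path.with_suffix(".json")
        payload = dict(provenance)
        payload["params"] = spectrum.params.to_dict()
        sidecar.write_text(json.dumps(payload, indent=1))
    return path


def read_spectrum(path, params: AcquisitionParams | None = None) -> Spectrum:
    path = Path(path)
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    if params is None:
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            params = AcquisitionParams.from_dict(
                json.loads(sidecar.read_text())["params"])
        else:
            params = AcquisitionParams()
    return Spectrum(arr[:, 1] + 1j * arr[:, 2], arr[:, 0], params)


def write_truth_table(path, truth: pd.DataFrame) -> Path:
    path = Path(path)
    truth.to_csv(path, index=False)
    return path


def read_truth_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
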