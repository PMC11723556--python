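"""Reading and writing timeseries, coefficient archives and transects.

Two input formats are supported for concentration data: an HDF5 file with
datasets ``/concentration`` (T x S) and ``/positions`` (S x 2) and root
attributes ``sample_rate`` and ``pitch``; or a delimited text file (one
column per source) with a JSON sidecar of the same basename carrying the
metadata.  Coefficient archives record the window configuration used.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .flowstats import VelocityTransect
from .spectral import TimeSeriesSet, TrigCoefficients, WindowSpec

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_coefficients",
    "write_coefficients",
    "read_transect",
    "write_transect",
]


def _h5_create(group, name, data):
    group.create_dataset(name, data=data, track_times=False)


def write_timeseries(series: TimeSeriesSet, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            _h5_create(f, "concentration", series.values)
            _h5_create(f, "positions", series.positions)
            f.attrs["sample_rate"] = series.sample_rate
            f.attrs["pitch"] = series.pitch
            f.attrs["label"] = series.label
    else:
        pd.DataFrame(series.values).to_csv(path, index=False, header=False)
        meta = {
            "sample_rate": series.sample_rate,
            "pitch": series.pitch,
            "label": series.label,
            "positions": series.positions.tolist(),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_timeseries(path: str | Path) -> TimeSeriesSet:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return TimeSeriesSet(
                values=f["concentration"][()],
                positions=f["positions"][()],
                sample_rate=float(f.attrs["sample_rate"]),
                pitch=float(f.attrs.get("pitch", 1.0)),
                label=str(f.attrs.get("label", "")),
            )
    values = pd.read_csv(path, header=None).to_numpy(dtype=float)
    meta = json.loads(path.with_suffix(".json").read_text())
    return TimeSeriesSet(
        values=values,
        positions=np.asarray(meta["positions"], dtype=float),
        sample_rate=float(meta["sample_rate"]),
        pitch=float(meta.get("pitch", 1.0)),
        label=str(meta.get("label", "")),
    )


def write_coefficients(coeffs: TrigCoefficients, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        _h5_create(f, "coeffs", coeffs.coeffs)
        _h5_create(f, "valid", coeffs.valid)
        f.attrs["segment_length"] = coeffs.segment_length
        f.attrs["sample_rate"] = coeffs.sample_rate
        f.attrs["window_length_s"] = coeffs.window.length_s
        f.attrs["window_shape"] = coeffs.window.shape
        f.attrs["window_overlap"] = coeffs.window.overlap
        f.attrs["window_beta"] = coeffs.window.beta


def read_coefficients(path: str | Path) -> TrigCoefficients:
    with h5py.File(path, "r") as f:
        window = WindowSpec(
            length_s=float(f.attrs["window_length_s"]),
            shape=str(f.attrs["window_shape"]),
            overlap=float(f.attrs["window_overlap"]),
            beta=float(f.attrs["window_beta"]),
        )
        return TrigCoefficients(
            coeffs=f["coeffs"][()],
            valid=f["valid"][()].astype(bool),
            segment_length=int(f.attrs["segment_length"]),
            sample_rate=float(f.attrs["sample_rate"]),
            window=window,
        )


def write_transect(transect: VelocityTransect, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        _h5_create(f, "u_pos", transect.u_pos)
        if transect.u_neg is not None:
            _h5_create(f, "u_neg", transect.u_neg)
        f.attrs["dr"] = transect.dr
        f.attrs["axis"] = transect.axis


def read_transect(path: str | Path) -> VelocityTransect:
    with h5py.File(path, "r") as f:
        return VelocityTransect(
            u_pos=f["u_pos"][()],
            u_neg=f["u_neg"][()] if "u_neg" in f else None,
            dr=float(f.attrs["dr"]),
            axis=str(f.attrs.get("axis", "y")),
        )
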