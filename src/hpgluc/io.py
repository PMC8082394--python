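"""On-disk containers.

Datasets live in an HDF5 file with groups ``/meta`` (JSON-encoded provenance
attributes), ``/spectra`` (complex array: time x [row x col x] points),
``/axis`` (ppm values) and ``/masks``; peak tables are exported as flat CSV
(time_s, metabolite, area, height, snr) for interoperability.
"""

from __future__ import annotations

import json
from typing import Optional, Union

import h5py
import numpy as np
import pandas as pd

from .epsi import EPSIDataset
from .spectra import DynamicSpectrumSeries, NoiseEstimate, PeakWindow, \
    integrate_peak, snr as _snr

__all__ = ["save_dataset", "load_dataset", "peak_table", "save_peak_table"]


def save_dataset(path, dataset: Union[DynamicSpectrumSeries, EPSIDataset]) -> None:
    """Write a single-voxel series or an EPSI grid to HDF5."""
    with h5py.File(path, "w") as fh:
        meta = fh.create_group("meta")
        if isinstance(dataset, EPSIDataset):
            meta.attrs["kind"] = "epsi"
            meta.attrs["voxel_size_mm"] = list(dataset.voxel_size_mm)
            meta.attrs["slice_thickness_mm"] = dataset.slice_thickness_mm
            masks = fh.create_group("masks")
            for name, m in dataset.masks.items():
                masks.create_dataset(name, data=m.astype(np.uint8))
        else:
            meta.attrs["kind"] = "series"
        meta.attrs["TR_s"] = dataset.TR_s
        meta.attrs["t0_s"] = dataset.t0_s
        meta.attrs["json"] = json.dumps(dataset.meta)
        fh.create_dataset("spectra", data=dataset.values)
        fh.create_dataset("axis", data=dataset.axis_ppm)


def load_dataset(path) -> Union[DynamicSpectrumSeries, EPSIDataset]:
    with h5py.File(path, "r") as fh:
        meta = fh["meta"].attrs
        kind = meta["kind"]
        values = fh["spectra"][()]
        axis = fh["axis"][()]
        extra = json.loads(meta.get("json", "{}"))
        if kind == "series":
            return DynamicSpectrumSeries(values, axis, float(meta["TR_s"]),
                                         float(meta["t0_s"]), extra)
        masks = {name: fh["masks"][name][()].astype(bool)
                 for name in fh["masks"]}
        return EPSIDataset(
            values=values, axis_ppm=axis, TR_s=float(meta["TR_s"]),
            t0_s=float(meta["t0_s"]),
            voxel_size_mm=tuple(meta["voxel_size_mm"]),
            slice_thickness_mm=float(meta["slice_thickness_mm"]),
            masks=masks, meta=extra)


def peak_table(
    series: DynamicSpectrumSeries,
    windows,
    noise: Optional[NoiseEstimate] = None,
) -> pd.DataFrame:
    """Per-timepoint area, height and (if noise given) SNR per metabolite."""
    rows = []
    for i, t in enumerate(series.times_s):
        spec = series[i]
        for w in windows:
            mask = (spec.axis_ppm >= w.lo_ppm) & (spec.axis_ppm <= w.hi_ppm)
            height = float(spec.real[mask].max())
            rows.append({
                "time_s": float(t),
                "metabolite": w.name,
                "area": integrate_peak(spec, w),
                "height": height,
                "snr": _snr(spec, w, noise) if noise and noise.sigma > 0
                       else np.nan,
            })
    return pd.DataFrame(rows)


def save_peak_table(path, series: DynamicSpectrumSeries, windows,
                    noise: Optional[NoiseEstimate] = None) -> None:
    peak_table(series, windows, noise).to_csv(path, index=False)
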