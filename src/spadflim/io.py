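"""File formats: histogram CSV, frame-stack and calibration HDF5, results CSV.

Histogram CSV dialect: header ``bin_index,time_ns,counts`` with 1-based bin
indices and bin-centre times.  Frame stacks are HDF5 with a ``/frames``
dataset (frame x row x col x bin), grid attributes on ``/grid``, and optional
simulator ground truth under ``/truth``.  Calibration files carry
``/peak_positions``, ``/hot_mask`` and a ``reference_bin`` attribute.
"""

from __future__ import annotations

from collections.abc import Sequence
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .calibration import PixelCalibration
from .core import DecayHistogram, PixelArrayFrame, SimGrid

__all__ = [
    "read_histogram",
    "write_histogram",
    "read_frames",
    "write_frames",
    "read_calibration",
    "write_calibration",
]


def write_histogram(hist: DecayHistogram, path: str | Path) -> None:
    n = hist.grid.n_bins
    df = pd.DataFrame(
        {
            "bin_index": np.arange(1, n + 1),
            "time_ns": hist.times_ns,
            "counts": hist.counts,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")  # lossless round trip


def read_histogram(path: str | Path) -> DecayHistogram:
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["bin_index", "time_ns", "counts"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if (df["counts"] < 0).any():
        row = int(df.index[df["counts"] < 0][0]) + 2  # +2: header and 1-based rows
        raise ValueError(f"{path}: negative count at row {row}")
    idx = df["bin_index"].to_numpy()
    if not np.array_equal(idx, np.arange(1, len(df) + 1)):
        raise ValueError(f"{path}: bin_index must run 1..n_bins contiguously")
    t = df["time_ns"].to_numpy(dtype=float)
    h = 2.0 * t[0]  # time_ns = (bin_index - 0.5) * h
    grid = SimGrid(n_bins=len(df), bin_width_ns=float(h))
    if not np.allclose(t, grid.bin_centers_ns, rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: time_ns column is not a uniform bin-centre axis")
    return DecayHistogram(counts=df["counts"].to_numpy(dtype=float), grid=grid)


def write_frames(frames: Sequence[PixelArrayFrame], path: str | Path) -> None:
    if len(frames) == 0:
        raise ValueError("no frames to write")
    grid = frames[0].grid
    stack = np.stack([f.per_pixel_counts for f in frames])
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=stack, compression="gzip", compression_opts=1)
        g = f.create_group("grid")
        g.attrs["n_bins"] = grid.n_bins
        g.attrs["bin_width_ns"] = grid.bin_width_ns
        if frames[0].true_peak_offsets is not None:
            f.create_dataset("truth/peak_offsets", data=frames[0].true_peak_offsets)
        if frames[0].true_hot_mask is not None:
            f.create_dataset("truth/hot_mask", data=frames[0].true_hot_mask)


def read_frames(path: str | Path) -> list[PixelArrayFrame]:
    with h5py.File(path, "r") as f:
        if "frames" not in f:
            raise ValueError(f"{path}: missing /frames dataset")
        if "grid" not in f:
            raise ValueError(f"{path}: missing /grid group")
        for attr in ("n_bins", "bin_width_ns"):
            if attr not in f["grid"].attrs:
                raise ValueError(f"{path}: /grid missing attribute {attr!r}")
        grid = SimGrid(
            n_bins=int(f["grid"].attrs["n_bins"]),
            bin_width_ns=float(f["grid"].attrs["bin_width_ns"]),
        )
        stack = f["frames"][...]
        offsets = f["truth/peak_offsets"][...] if "truth/peak_offsets" in f else None
        hot = f["truth/hot_mask"][...] if "truth/hot_mask" in f else None
    return [
        PixelArrayFrame(
            per_pixel_counts=frame, grid=grid,
            true_peak_offsets=offsets, true_hot_mask=hot,
        )
        for frame in stack
    ]


def write_calibration(calib: PixelCalibration, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("peak_positions", data=calib.peak_positions)
        f.create_dataset("hot_mask", data=calib.hot_mask)
        f.attrs["reference_bin"] = calib.reference_bin


def read_calibration(path: str | Path) -> PixelCalibration:
    with h5py.File(path, "r") as f:
        for name in ("peak_positions", "hot_mask"):
            if name not in f:
                raise ValueError(f"{path}: missing /{name}")
        if "reference_bin" not in f.attrs:
            raise ValueError(f"{path}: missing attribute 'reference_bin'")
        return PixelCalibration(
            peak_positions=f["peak_positions"][...],
            hot_mask=f["hot_mask"][...].astype(bool),
            reference_bin=int(f.attrs["reference_bin"]),
        )
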