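"""Serialization: HDF5 cubes and images, CSV exports, JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .forward import RadarDataCube
from .imaging import ImageGrid, VoxelImage
from .mmode import MModeSeries

__all__ = [
    "CubeFormatError",
    "save_cube",
    "load_cube",
    "cube_to_csv",
    "save_image",
    "load_image",
    "save_series_csv",
    "save_png_preview",
    "write_json",
]


class CubeFormatError(ValueError):
    """Raised when an on-disk container does not match the expected layout."""


_CUBE_DATASETS = ("data", "fast_time_s", "slow_time_s", "channel_tx", "channel_rx")


def save_cube(cube: RadarDataCube, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=cube.data)
        f.create_dataset("fast_time_s", data=cube.fast_time_axis)
        f.create_dataset("slow_time_s", data=cube.slow_time_axis)
        f.create_dataset("channel_tx", data=cube.channel_tx)
        f.create_dataset("channel_rx", data=cube.channel_rx)
        f.attrs["compressed"] = bool(cube.compressed)
        for k, v in cube.attrs.items():
            if v is not None:
                f.attrs[k] = v
    return path


def load_cube(path) -> RadarDataCube:
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            missing = [name for name in _CUBE_DATASETS if name not in f]
            if missing:
                raise CubeFormatError(f"{path}: missing datasets {missing}")
            data = f["data"][()]
            fast = f["fast_time_s"][()]
            slow = f["slow_time_s"][()]
            tx = f["channel_tx"][()]
            rx = f["channel_rx"][()]
            attrs = {k: v for k, v in f.attrs.items() if k != "compressed"}
            compressed = bool(f.attrs.get("compressed", False))
    except OSError as exc:
        raise CubeFormatError(f"{path}: not a readable HDF5 cube ({exc})") from exc
    try:
        return RadarDataCube(
            data=data,
            fast_time_axis=fast,
            slow_time_axis=slow,
            channel_tx=tx,
            channel_rx=rx,
            compressed=compressed,
            attrs=dict(attrs),
        )
    except ValueError as exc:
        raise CubeFormatError(f"{path}: inconsistent cube layout ({exc})") from exc


def cube_to_csv(cube: RadarDataCube, path) -> Path:
    """Long-format CSV export (one row per sample); for small cubes only."""
    path = Path(path)
    nf, ns, nc = cube.data.shape
    fast, slow, ch = np.meshgrid(
        cube.fast_time_axis, cube.slow_time_axis, np.arange(nc), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "fast_time_s": fast.ravel(),
            "slow_time_s": slow.ravel(),
            "channel": ch.ravel().astype(int),
            "tx": cube.channel_tx[ch.ravel()],
            "rx": cube.channel_rx[ch.ravel()],
            "value": cube.data.ravel(),
        }
    )
    df.to_csv(path, index=False)
    return path


def save_image(image: VoxelImage, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=image.values)
        f.create_dataset("axis0", data=image.grid.axis0)
        f.create_dataset("axis1", data=image.grid.axis1)
        f.attrs["plane"] = image.grid.plane
        f.attrs["plane_coord"] = image.grid.plane_coord
        for k, v in image.meta.items():
            if v is not None:
                f.attrs[k] = v
    return path


def load_image(path) -> VoxelImage:
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            for name in ("values", "axis0", "axis1"):
                if name not in f:
                    raise CubeFormatError(f"{path}: missing dataset {name}")
            values = f["values"][()]
            grid = ImageGrid(
                axis0=f["axis0"][()],
                axis1=f["axis1"][()],
                plane=str(f.attrs.get("plane", "lateral")),
                plane_coord=float(f.attrs.get("plane_coord", 0.0)),
            )
            meta = {
                k: v for k, v in f.attrs.items() if k not in ("plane", "plane_coord")
            }
    except OSError as exc:
        raise CubeFormatError(f"{path}: not a readable HDF5 image ({exc})") from exc
    return VoxelImage(values=values, grid=grid, meta=dict(meta))


def save_series_csv(series_list: list[MModeSeries], path, spectra_path=None):
    """Write M-mode series (and optionally spectra) for several probes."""
    path = Path(path)
    rows = {}
    rows["T_s"] = series_list[0].times
    for s in series_list:
        label = f"x{s.point[0] * 100:g}_y{s.point[1] * 100:g}_z{s.point[2] * 100:g}cm"
        rows[label] = s.series
    pd.DataFrame(rows).to_csv(path, index=False)
    if spectra_path is not None:
        srows = {"freq_hz": series_list[0].freqs}
        for s in series_list:
            label = f"x{s.point[0] * 100:g}_y{s.point[1] * 100:g}_z{s.point[2] * 100:g}cm"
            srows[label] = s.spectrum
        pd.DataFrame(srows).to_csv(Path(spectra_path), index=False)
    return path


def save_png_preview(image: VoxelImage, path, title: str = "") -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 4))
    extent = [
        image.grid.axis1[0] * 100,
        image.grid.axis1[-1] * 100,
        image.grid.axis0[0] * 100,
        image.grid.axis0[-1] * 100,
    ]
    ax.imshow(image.values, origin="lower", extent=extent, aspect="equal", cmap="jet")
    if image.grid.plane == "lateral":
        ax.set_xlabel("y (cm)")
        ax.set_ylabel("x (cm)")
    else:
        ax.set_xlabel("z (cm)")
        ax.set_ylabel("x (cm)")
    ax.set_title(title or f"{image.grid.plane} @ {image.grid.plane_coord * 100:g} cm")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def write_json(obj: dict, path) -> Path:
    """Deterministic JSON dump (sorted keys, repr floats)."""
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path
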