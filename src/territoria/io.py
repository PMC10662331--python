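"""Reading image stacks, maximal projection, and measurement tables.

All downstream analysis runs on 2D maximal projections of confocal z-stacks;
cultured myogenic nuclei are flat enough (a few microns) that projection
loses little axial information, and chromosome territories typically span
most of the z range anyway.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ChannelMapError, SchemaError, UserError

REQUIRED_CHANNELS = ("dapi", "paint")


@dataclass
class ImageStack:
    """A (z, c, y, x) intensity stack with named channels.

    ``pixel_size_um`` is the in-plane pixel size in microns, assumed
    isotropic in x and y.
    """

    voxels: np.ndarray
    channel_names: list[str]
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise UserError(f"stack must be 4D (z, c, y, x), got ndim={self.voxels.ndim}")
        if self.voxels.shape[0] < 1:
            raise UserError("stack must have at least one z slice")
        if self.voxels.shape[1] != len(self.channel_names):
            raise ChannelMapError(
                f"{len(self.channel_names)} channel names for "
                f"{self.voxels.shape[1]} channels"
            )
        for name in REQUIRED_CHANNELS:
            if name not in self.channel_names:
                raise ChannelMapError(f"required channel {name!r} missing")
        if not self.pixel_size_um > 0:
            raise UserError("pixel_size_um must be > 0")

    @property
    def n_z(self) -> int:
        return self.voxels.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ChannelMapError(f"unknown channel {name!r}") from None


@dataclass
class ChannelImage:
    """A single-channel 2D intensity image with pixel-size metadata."""

    pixels: np.ndarray
    pixel_size_um: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise UserError("ChannelImage requires a non-empty 2D array")
        if not np.all(np.isfinite(self.pixels.astype(float))):
            raise UserError("ChannelImage intensities must be finite")
        if np.any(self.pixels < 0):
            raise UserError("ChannelImage intensities must be >= 0")
        if not self.pixel_size_um > 0:
            raise UserError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def read_stack(
    path: str | Path,
    channel_map: dict[str, int],
    pixel_size_um: float,
    axes: str = "zcyx",
) -> ImageStack:
    """Read a TIFF/OME-TIFF as an :class:`ImageStack`.

    Parameters
    ----------
    path
        TIFF file holding a multi-channel stack.
    channel_map
        Mapping from channel label (must include ``"dapi"`` and ``"paint"``)
        to channel index in the file.
    pixel_size_um
        In-plane pixel size, from acquisition metadata or config.
    axes
        Order of the on-disk axes as a permutation of ``"zcyx"``; axes
        absent from the file (e.g. a single z slice stored as (c, y, x))
        may be omitted and are inserted with length 1.
    """
    path = Path(path)
    if not path.exists():
        raise UserError(f"file not found: {path}")
    arr = np.asarray(tifffile.imread(path))
    axes = axes.lower()
    if sorted(axes) != sorted(set(axes)) or any(a not in "zcyx" for a in axes):
        raise UserError(f"axes must be a subset-permutation of 'zcyx', got {axes!r}")
    if arr.ndim != len(axes):
        raise UserError(
            f"file has {arr.ndim} axes but axes spec {axes!r} names {len(axes)}"
        )
    # insert missing axes with length 1, then transpose to (z, c, y, x)
    for missing in [a for a in "zcyx" if a not in axes]:
        arr = arr[np.newaxis]
        axes = missing + axes
    arr = np.transpose(arr, [axes.index(a) for a in "zcyx"])

    n_ch = arr.shape[1]
    for name, idx in channel_map.items():
        if not (0 <= idx < n_ch):
            raise ChannelMapError(
                f"channel index {idx} for {name!r} out of range (file has {n_ch})"
            )
    names = [""] * n_ch
    for name, idx in channel_map.items():
        names[idx] = name
    for i, name in enumerate(names):
        if not name:
            names[i] = f"ch{i}"
    return ImageStack(voxels=arr, channel_names=names, pixel_size_um=pixel_size_um)


def max_project(stack: ImageStack, channel: str) -> ChannelImage:
    """Maximal projection of one channel along z."""
    idx = stack.channel_index(channel)
    pixels = np.max(stack.voxels[:, idx], axis=0)
    return ChannelImage(
        pixels=pixels, pixel_size_um=stack.pixel_size_um, channel_name=channel
    )


# Column schemas for the two measurement tables.  write_measurements checks
# that every required column is present; extra columns are allowed and kept.
NUCLEUS_COLUMNS = [
    "scene",
    "group",
    "nucleus",
    "area_px",
    "area_um2",
    "major_um",
    "minor_um",
    "eccentricity",
    "orientation_deg",
    "centroid_x",
    "centroid_y",
    "fragmentation_score",
    "fragmentation_class",
    "occupancy_fraction",
]
TERRITORY_COLUMNS = [
    "scene",
    "group",
    "nucleus",
    "territory",
    "area_px",
    "centroid_x",
    "centroid_y",
    "theta_deg",
    "axial_class",
    "r_fragment",
    "ring_index",
]


def write_measurements(
    records: pd.DataFrame, path: str | Path, required: list[str]
) -> None:
    """Write a measurement table to CSV with full float precision.

    Raises :class:`SchemaError` when a required column is missing; a
    header-only file is written for an empty table.
    """
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise SchemaError(f"measurement table missing columns: {missing}")
    path = Path(path)
    try:
        records.to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:
        raise UserError(f"cannot write {path}: {exc}") from exc


def read_measurements(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise UserError(f"file not found: {path}")
    return pd.read_csv(path, float_precision="round_trip")
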