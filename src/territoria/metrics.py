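"""Per-territory and per-nucleus measurements.

Covers the occupancy, DNA-density, and axial-orientation measures: the
fraction of nuclear area covered by territories of one chromosome, the
median-DAPI ratio between a territory and its whole nucleus (a proxy for
relative local DNA density that cancels staining/illumination scale), the
axial angle theta between the nuclear major axis and the centroid-to-
centroid vector with its 45/135-degree dichotomy, per-cell axial
classification, and homolog-pair distance/angle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from ._geometry import axial_angle_deg, is_major_parallel, vector_angle_deg
from .errors import DataError, SchemeMismatchError, UndefinedAngleError, UserError
from .io import ChannelImage
from .morphometry import NuclearShape
from .segment import NuclearMask, TerritoryMask

AxialClass = Literal["major_parallel", "minor_parallel"]


@dataclass
class AxialMeasurement:
    theta_deg: float  # [0, 180)
    axial_class: AxialClass


@dataclass
class CellAxialClass:
    scheme: Literal["normal", "tumor"]
    label: str  # normal: both_minor | one_plus_major; tumor: ge50_major | lt50_major


@dataclass
class DensityRatio:
    r_fragment: float


def area_occupancy(
    territories: Iterable[TerritoryMask], nucleus: NuclearMask
) -> float:
    """Fraction of the nuclear area covered by the territories' union.

    Overlapping territory pixels count once, and only pixels inside the
    nucleus count (territories are clipped to their nucleus).
    """
    union = np.zeros(nucleus.pixels.shape, dtype=bool)
    for terr in territories:
        union |= terr.pixels
    return float((union & nucleus.pixels).sum() / nucleus.pixels.sum())


def density_ratio(
    dapi: ChannelImage, territory: TerritoryMask, nucleus: NuclearMask
) -> DensityRatio:
    """R = median DAPI within the territory / median DAPI within its nucleus.

    Invariant to rescaling the DAPI channel by any positive constant.
    """
    img = dapi.pixels.astype(float)
    if territory.pixels.sum() == 0 or nucleus.pixels.sum() == 0:
        raise UserError("empty mask")
    med_nuc = float(np.median(img[nucleus.pixels]))
    if med_nuc == 0:
        raise DataError("zero nuclear median DAPI; ratio undefined")
    med_terr = float(np.median(img[territory.pixels]))
    return DensityRatio(r_fragment=med_terr / med_nuc)


def axial_angle(
    territory_centroid_xy: tuple[float, float], shape: NuclearShape
) -> AxialMeasurement:
    """Axial angle of a territory and its major/minor dichotomy.

    theta is measured between the undirected major-axis line and the vector
    from the nuclear centroid to the territory centroid, folded to
    [0, 180).  Angles <= 45 or >= 135 (boundaries included) classify as
    major-parallel.  Coincident centroids raise
    :class:`UndefinedAngleError` (the territory is excluded from axial
    statistics).
    """
    dx = territory_centroid_xy[0] - shape.centroid_xy[0]
    dy = territory_centroid_xy[1] - shape.centroid_xy[1]
    if dx == 0 and dy == 0:
        raise UndefinedAngleError("territory centroid coincides with nuclear centroid")
    theta = axial_angle_deg(vector_angle_deg(dx, dy), shape.orientation_deg)
    cls: AxialClass = "major_parallel" if is_major_parallel(theta) else "minor_parallel"
    return AxialMeasurement(theta_deg=theta, axial_class=cls)


def classify_cell(
    measurements: list[AxialMeasurement], scheme: Literal["normal", "tumor"]
) -> CellAxialClass:
    """Per-cell axial classification.

    normal (diploid expectation, exactly two homologs): ``both_minor`` iff
    both territories are minor-parallel, else ``one_plus_major``.

    tumor (variable signal counts): ``ge50_major`` iff at least half of the
    measured territories are major-parallel, else ``lt50_major``.
    """
    if not measurements:
        raise SchemeMismatchError("at least one axial measurement required")
    n_major = sum(1 for m in measurements if m.axial_class == "major_parallel")
    if scheme == "normal":
        if len(measurements) != 2:
            raise SchemeMismatchError(
                f"normal scheme expects exactly 2 measurements, got {len(measurements)}"
            )
        label = "both_minor" if n_major == 0 else "one_plus_major"
    elif scheme == "tumor":
        label = "ge50_major" if n_major / len(measurements) >= 0.5 else "lt50_major"
    else:
        raise UserError(f"unknown scheme {scheme!r}")
    return CellAxialClass(scheme=scheme, label=label)


def inter_territory_distance(
    c1_xy: tuple[float, float], c2_xy: tuple[float, float], pixel_size_um: float
) -> float:
    """Euclidean centroid-to-centroid distance in microns (homolog pairs)."""
    if not pixel_size_um > 0:
        raise UserError("pixel_size_um must be > 0")
    return float(np.hypot(c1_xy[0] - c2_xy[0], c1_xy[1] - c2_xy[1])) * pixel_size_um


def inter_territory_angle(
    c1_xy: tuple[float, float],
    c2_xy: tuple[float, float],
    nuclear_centroid_xy: tuple[float, float],
) -> float:
    """Angle at the nuclear centroid between the two centroid vectors, [0, 180]."""
    v1 = np.subtract(c1_xy, nuclear_centroid_xy)
    v2 = np.subtract(c2_xy, nuclear_centroid_xy)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise UndefinedAngleError("a territory centroid coincides with the nuclear centroid")
    cosang = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def pair_measurements(
    territories: list[TerritoryMask],
    shape: NuclearShape,
    pixel_size_um: float,
) -> tuple[float, float]:
    """(distance_um, angle_deg) for a nucleus with exactly two territories."""
    if len(territories) != 2:
        raise UserError("pair measurements require exactly 2 territories")
    c1, c2 = territories[0].centroid_xy, territories[1].centroid_xy
    return (
        inter_territory_distance(c1, c2, pixel_size_um),
        inter_territory_angle(c1, c2, shape.centroid_xy),
    )
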