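"""Per-nucleus shape descriptors and fragmentation scoring.

Axis lengths come from the moment-equivalent ellipse of the binary mask
(the ellipse with matching second central moments, the CellProfiler
convention) and are reported as full lengths in microns.  Orientation is
the math-convention angle of the major axis folded to [0, 180); centroids
are unweighted mask centroids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
from skimage.measure import regionprops

from ._geometry import mask_orientation_deg
from .errors import UserError
from .segment import NuclearMask, TerritoryMask


@dataclass
class NuclearShape:
    centroid_xy: tuple[float, float]  # px, (x, y)
    major_axis_um: float
    minor_axis_um: float
    area_um2: float
    eccentricity: float
    orientation_deg: float  # [0, 180)


@dataclass
class FragmentationRecord:
    nucleus: int
    score: int
    dichotomy: Literal["<=2", ">2"]


def nucleus_morphometry(
    mask: NuclearMask | np.ndarray,
    pixel_size_um: float,
    intensity: np.ndarray | None = None,
) -> NuclearShape:
    """Shape descriptors of one nuclear mask.

    The reported eccentricity satisfies
    ``ecc = sqrt(1 - (minor/major)**2)`` to numerical precision because
    both derive from the same second-moment ellipse.  The centroid is the
    unweighted mask centroid by default; pass ``intensity`` (e.g. the DAPI
    image) for an intensity-weighted centroid in sensitivity analyses.
    """
    pixels = mask.pixels if isinstance(mask, NuclearMask) else np.asarray(mask)
    if pixels.sum() == 0:
        raise UserError("empty mask")
    if not pixel_size_um > 0:
        raise UserError("pixel_size_um must be > 0")
    rp = regionprops(pixels.astype(np.uint8), intensity_image=intensity)[0]
    cy, cx = rp.centroid_weighted if intensity is not None else rp.centroid
    return NuclearShape(
        centroid_xy=(float(cx), float(cy)),
        major_axis_um=float(rp.axis_major_length) * pixel_size_um,
        minor_axis_um=float(rp.axis_minor_length) * pixel_size_um,
        area_um2=float(rp.area) * pixel_size_um**2,
        eccentricity=float(rp.eccentricity),
        orientation_deg=mask_orientation_deg(pixels),
    )


def fragmentation_score(
    territories: Iterable[TerritoryMask],
    nucleus: int,
    known_nuclei: Iterable[int] | None = None,
) -> FragmentationRecord:
    """Number of assigned territories of one chromosome in one nucleus.

    The dichotomy follows the two-or-fewer convention used to separate
    euploid-looking nuclei from fragmented/aneuploid ones: "<=2" vs ">2".
    """
    if known_nuclei is not None and nucleus not in set(known_nuclei):
        raise UserError(f"unknown nucleus label {nucleus}")
    score = sum(
        1 for t in territories if not t.unassigned and t.parent_nucleus == nucleus
    )
    return FragmentationRecord(
        nucleus=nucleus, score=score, dichotomy="<=2" if score <= 2 else ">2"
    )
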