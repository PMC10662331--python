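"""Nuclear and territory segmentation.

Nuclear masks come from the DAPI channel: non-local-means smoothing to even
out staining, a Kapur maximum-entropy threshold, then a morphological
closing (2-px dilation followed by 2-px erosion) to undo boundary artifacts
of the smoothing.  Connected components larger than 10,000 px or touching
the image frame are discarded; a small-debris floor (default 500 px) is
configurable and can be disabled.

Territory masks come from the paint channel: a 2-px-radius median filter,
then a Kapur threshold whose histogram is restricted to pixels inside the
union of nuclear masks (so the cut separates territory from intranuclear
background rather than from the dark extracellular field), then a
100–10,000 px component size filter (bounds inclusive).

The Kapur threshold itself is implemented here from the histogram up: it is
the level maximizing the summed Shannon entropies of the two classes
(Kapur–Sahoo–Wong criterion), with ties broken toward the lower level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import filters as skfilters
from skimage import morphology, restoration
from skimage.measure import label as sklabel

from .errors import DegenerateHistogramError, UserError
from .io import ChannelImage


@dataclass
class NuclearMask:
    label: int
    pixels: np.ndarray  # full-frame boolean mask
    area_px: int
    touches_border: bool


@dataclass
class TerritoryMask:
    label: int
    pixels: np.ndarray
    area_px: int
    parent_nucleus: int | None = None
    unassigned: bool = False

    @property
    def centroid_xy(self) -> tuple[float, float]:
        rows, cols = np.nonzero(self.pixels)
        return float(cols.mean()), float(rows.mean())


@dataclass
class SegmentationParams:
    """Tunable knobs of the segmentation recipe.

    Fixed-by-recipe values (closing radius 2, median radius 2, the
    100–10,000 px territory band, the 10,000 px nuclear ceiling, border
    exclusion) default to the recipe; the non-local-means patch geometry and
    the debris floor are genuinely free and exposed.
    """

    nlm_patch_size: int = 3
    nlm_patch_distance: int = 7
    nlm_h: float | None = None  # None = 0.8 * estimated noise sigma
    closing_radius: int = 2
    median_radius: int = 2
    n_bins: int = 256
    nucleus_max_area_px: int = 10_000
    nucleus_min_area_px: int | None = 500  # None disables the debris floor
    territory_min_area_px: int = 100
    territory_max_area_px: int = 10_000


def kapur_threshold(histogram: np.ndarray) -> int:
    """Kapur maximum-entropy threshold of an intensity histogram.

    Returns the level ``t`` (bin index) maximizing
    ``H({<=t}) + H({>t})``, where H is the Shannon entropy of the
    class-normalized bin probabilities.  Ties break toward the lower level.
    Raises :class:`DegenerateHistogramError` when fewer than two bins are
    occupied (constant image).
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.ndim != 1 or hist.size < 2:
        raise UserError("histogram must be a 1D array with >= 2 bins")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("histogram has fewer than 2 occupied bins")
    p = hist / hist.sum()
    cum = np.cumsum(p)
    logp = np.log(p, where=p > 0, out=np.zeros_like(p))
    plogp = p * logp
    s = np.cumsum(plogp)  # sum_{i<=t} p_i ln p_i  (<= 0)
    s_total = s[-1]
    # candidate thresholds: both classes must carry probability mass
    t = np.arange(hist.size - 1)
    p0 = cum[:-1]
    valid = (p0 > 0) & (p0 < 1)
    crit = np.full(hist.size - 1, -np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        h0 = np.log(p0) - s[:-1] / p0
        h1 = np.log1p(-p0) - (s_total - s[:-1]) / (1.0 - p0)
    crit[valid] = (h0 + h1)[valid]
    # ties break toward the lower level; a small tolerance keeps analytically
    # tied levels (e.g. symmetric histograms) stable under float noise
    return int(t[crit >= crit.max() - 1e-9][0])


def kapur_threshold_image(pixels: np.ndarray, n_bins: int = 256) -> float:
    """Kapur threshold of an image, returned as an intensity cut value.

    The histogram spans [min, max] in ``n_bins`` equal bins; foreground is
    ``pixels > value``.  Pass a subset of pixels (e.g. intranuclear ones) to
    restrict the histogram.
    """
    flat = np.asarray(pixels, dtype=float).ravel()
    lo, hi = float(flat.min()), float(flat.max())
    if hi <= lo:
        raise DegenerateHistogramError("constant image")
    hist, edges = np.histogram(flat, bins=n_bins, range=(lo, hi))
    t = kapur_threshold(hist)
    return float(edges[t + 1])


def _components(binary: np.ndarray) -> list[tuple[int, np.ndarray, int]]:
    labels = sklabel(binary, connectivity=2)
    out = []
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        out.append((lab, mask, int(mask.sum())))
    return out


def _touches_border(mask: np.ndarray) -> bool:
    return bool(
        mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
    )


@dataclass
class SegmentationLog:
    """Objects dropped by the filters, with reason codes."""

    excluded: list[tuple[int, int, str]] = field(default_factory=list)  # label, area, reason

    def add(self, label: int, area: int, reason: str) -> None:
        self.excluded.append((label, area, reason))


def segment_nuclei(
    dapi: ChannelImage,
    params: SegmentationParams | None = None,
    log: SegmentationLog | None = None,
) -> list[NuclearMask]:
    """Segment nuclei from a DAPI projection.

    Pipeline: non-local-means smoothing -> Kapur threshold -> radius-2
    closing -> connected components -> drop components above 10,000 px,
    touching the frame, or (configurably) below the debris floor.
    """
    params = params or SegmentationParams()
    img = dapi.pixels.astype(float)
    sigma = float(restoration.estimate_sigma(img))
    if np.isfinite(sigma) and sigma > 0:
        h = params.nlm_h if params.nlm_h is not None else 0.8 * sigma
        img = restoration.denoise_nl_means(
            img,
            patch_size=params.nlm_patch_size,
            patch_distance=params.nlm_patch_distance,
            h=h,
            sigma=sigma,
            fast_mode=True,
        )
    cut = kapur_threshold_image(img, params.n_bins)
    binary = img > cut
    binary = morphology.closing(
        binary, footprint=morphology.disk(params.closing_radius)
    )
    retained = []
    for lab, mask, area in _components(binary):
        if area > params.nucleus_max_area_px:
            if log:
                log.add(lab, area, "TOO_LARGE")
            continue
        if _touches_border(mask):
            if log:
                log.add(lab, area, "BORDER")
            continue
        if params.nucleus_min_area_px is not None and area < params.nucleus_min_area_px:
            if log:
                log.add(lab, area, "TOO_SMALL")
            continue
        retained.append(
            NuclearMask(label=len(retained) + 1, pixels=mask, area_px=area, touches_border=False)
        )
    return retained


def segment_territories(
    paint: ChannelImage,
    params: SegmentationParams | None = None,
    nuclei: list[NuclearMask] | None = None,
    log: SegmentationLog | None = None,
) -> list[TerritoryMask]:
    """Segment paint territories.

    Pipeline: radius-2 median filter -> Kapur threshold (histogram
    restricted to intranuclear pixels when nuclear masks are supplied) ->
    connected components -> keep areas in [100, 10,000] px inclusive.
    """
    params = params or SegmentationParams()
    img = paint.pixels.astype(float)
    med = skfilters.median(img, footprint=morphology.disk(params.median_radius))
    if nuclei:
        union = np.zeros(img.shape, dtype=bool)
        for nuc in nuclei:
            union |= nuc.pixels
        source = med[union]
    else:
        source = med
    cut = kapur_threshold_image(source, params.n_bins)
    binary = med > cut
    retained = []
    for lab, mask, area in _components(binary):
        if not params.territory_min_area_px <= area <= params.territory_max_area_px:
            if log:
                reason = "TOO_SMALL" if area < params.territory_min_area_px else "TOO_LARGE"
                log.add(lab, area, reason)
            continue
        retained.append(TerritoryMask(label=len(retained) + 1, pixels=mask, area_px=area))
    return retained


def assign_to_nuclei(
    territories: list[TerritoryMask], nuclei: list[NuclearMask]
) -> list[TerritoryMask]:
    """Assign each territory to a parent nucleus (in place; also returned).

    A territory belongs to the nucleus containing its centroid; failing
    that, to the nucleus holding >= 50% of its pixels.  Otherwise it is
    flagged unassigned and excluded downstream.
    """
    if nuclei:
        label_img = np.zeros(nuclei[0].pixels.shape, dtype=int)
        for nuc in nuclei:
            label_img[nuc.pixels] = nuc.label
    for terr in territories:
        terr.parent_nucleus = None
        terr.unassigned = True
        if not nuclei:
            continue
        x, y = terr.centroid_xy
        iy, ix = int(round(y)), int(round(x))
        if 0 <= iy < label_img.shape[0] and 0 <= ix < label_img.shape[1]:
            lab = int(label_img[iy, ix])
            if lab > 0:
                terr.parent_nucleus = lab
                terr.unassigned = False
                continue
        shares = [(int((terr.pixels & nuc.pixels).sum()), nuc.label) for nuc in nuclei]
        best_share, best_label = max(shares)
        if best_share / terr.area_px >= 0.5:
            terr.parent_nucleus = best_label
            terr.unassigned = False
    return territories
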