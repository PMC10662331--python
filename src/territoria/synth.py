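"""Synthetic two-channel scenes (DAPI + chromosome paint) with ground truth.

The generator emulates the statistical structure of confocal projections of
cultured myogenic / rhabdomyosarcoma nuclei:

* elliptical nuclei, full major axes around 12–16 um and eccentricities
  around 0.7–0.85 at the default pixel size of 0.13 um/px;
* DAPI intensity rising toward the nuclear periphery, modelled as
  ``base + (peak - base) * rho**exponent`` where ``rho`` is normalized
  distance from center (0) to edge (1);
* 1–8 compact paint territories per nucleus, each a few percent of the
  nuclear area, with a controllable radial placement law and a controllable
  angular concentration toward the major nuclear axis;
* a territory-specific DAPI multiplier (``dapi_contrast``), the ground truth
  for the territory/nucleus DNA-density ratio.

Normalized radial position shares its definition with the ring partition in
:mod:`territoria.radial` (``rho = 1 - d_edge / d_edge_max``), so generator
truth and pipeline measurement live in one coordinate system.  Angular
placement uses a von Mises distribution on ``2*theta`` (axis-symmetric,
wrapped); concentration 0 is exactly uniform on [0, 180).

Everything is deterministic given a seed; per-scene seeds in a cohort are
derived from the master seed with :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage, stats

from ._geometry import axial_angle_deg, fold_180
from .errors import PlacementError, UserError
from .io import ChannelImage

DEFAULT_PIXEL_SIZE_UM = 0.13


class NucleusSpec(BaseModel):
    """Geometry and DAPI model of one synthetic nucleus."""

    center: tuple[float, float] | None = None  # (x, y) px; None = frame center
    semi_major_px: float = 49.0
    semi_minor_px: float = 33.0
    orientation_deg: float = 0.0  # math convention, [0, 180)
    dapi_gradient_exponent: float = Field(default=1.0, ge=0.0)
    # a moderate (~1.6x) center-to-periphery DAPI rise: strong enough to show
    # the peripheral DNA-density pattern, mild enough that an entropy
    # threshold separates nucleus from background rather than dim from
    # bright nucleoplasm
    base_intensity: float = 70.0
    peak_intensity: float = 115.0

    @model_validator(mode="after")
    def _check(self) -> "NucleusSpec":
        if self.semi_major_px <= 0 or self.semi_minor_px <= 0:
            raise ValueError("semi-axes must be positive")
        if self.semi_minor_px > self.semi_major_px:
            raise ValueError("semi_minor_px must be <= semi_major_px")
        return self


class RadialLaw(BaseModel):
    """Named distribution over normalized radial position in [0, 1]."""

    family: Literal["uniform", "beta", "fixed"] = "beta"
    a: float = 2.5
    b: float = 1.5
    value: float = 0.5  # used by "fixed"

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "uniform":
            return rng.uniform(0.0, 1.0, size=n)
        if self.family == "beta":
            return rng.beta(self.a, self.b, size=n)
        return np.full(n, float(self.value))


class PlacementSpec(BaseModel):
    """How territories of one chromosome are placed within a nucleus.

    ``territory_area_fraction`` is the area of a single territory as a
    fraction of the nuclear area; ``paint_contrast`` is the territory paint
    intensity over the paint background; ``dapi_contrast`` multiplies the
    DAPI model within territory pixels (truth for the density ratio).
    """

    n_territories: int = Field(default=2, ge=0)
    radial_law: RadialLaw = RadialLaw()
    angular_concentration: float = Field(default=0.0, ge=0.0)
    territory_area_fraction: float = Field(default=0.03, gt=0.0, lt=1.0)
    paint_contrast: float = Field(default=4.0, gt=0.0)
    dapi_contrast: float = Field(default=1.1, gt=0.0)

    @model_validator(mode="after")
    def _check(self) -> "PlacementSpec":
        if self.n_territories * self.territory_area_fraction >= 1.0:
            raise ValueError("total territory area must be below the nucleus area")
        return self


class NoiseSpec(BaseModel):
    """Render-time noise: additive Gaussian on both channels + backgrounds."""

    sigma: float = Field(default=2.0, ge=0.0)
    dapi_background: float = Field(default=5.0, ge=0.0)
    paint_background: float = Field(default=20.0, gt=0.0)


def sample_axial_angles(
    n: int, concentration: float, rng: np.random.Generator
) -> np.ndarray:
    """Sample axial angles theta in [0, 180) about the major-axis line.

    ``2*theta`` follows a von Mises distribution with the given
    concentration centred on the axis; concentration 0 yields theta exactly
    uniform on [0, 180).  As concentration grows, mass piles up at 0/180
    (major-parallel).
    """
    if concentration == 0.0:
        doubled = rng.uniform(-np.pi, np.pi, size=n)
    else:
        doubled = stats.vonmises.rvs(concentration, size=n, random_state=rng)
    return fold_180(np.degrees(doubled / 2.0))


def concentration_for_major_fraction(p_major: float) -> float:
    """Von Mises concentration giving P(major-parallel) = ``p_major``.

    Solves P(|delta| <= 45 deg) = p_major for ``2*delta ~ VM(kappa)``.
    ``p_major`` must lie in [0.5, 1); 0.5 maps to concentration 0.
    """
    if not 0.5 <= p_major < 1.0:
        raise UserError("p_major must be in [0.5, 1)")
    if p_major == 0.5:
        return 0.0
    from scipy.optimize import brentq

    def gap(kappa: float) -> float:
        return (
            stats.vonmises.cdf(np.pi / 2, kappa)
            - stats.vonmises.cdf(-np.pi / 2, kappa)
            - p_major
        )

    return float(brentq(gap, 1e-9, 500.0))


def _ellipse_mask(
    shape: tuple[int, int],
    center_xy: tuple[float, float],
    a: float,
    b: float,
    orientation_deg: float,
) -> np.ndarray:
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    u = cols - center_xy[0]
    v = -(rows - center_xy[1])  # y-up frame
    th = np.radians(orientation_deg)
    xr = u * np.cos(th) + v * np.sin(th)
    yr = -u * np.sin(th) + v * np.cos(th)
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def _rho_map(mask: np.ndarray) -> tuple[np.ndarray, float]:
    """Normalized radial position 1 - d_edge/d_edge_max over a mask."""
    d = ndimage.distance_transform_edt(mask)
    dmax = float(d.max())
    rho = np.zeros_like(d, dtype=float)
    rho[mask] = 1.0 - d[mask] / dmax
    return rho, dmax


def generate_nucleus(
    spec: NucleusSpec, image_shape: tuple[int, int], seed: int | None = None
) -> tuple[np.ndarray, ChannelImage]:
    """Render one nucleus: binary mask + noiseless analytic DAPI image.

    DAPI at normalized radial position rho is
    ``base + (peak - base) * rho**exponent`` (uniform when the exponent is
    0).  Noise is added later, at scene render time.  Deterministic given
    the spec (the seed parameter is accepted for interface symmetry).
    """
    h, w = image_shape
    cx, cy = spec.center if spec.center is not None else ((w - 1) / 2, (h - 1) / 2)
    mask = _ellipse_mask(image_shape, (cx, cy), spec.semi_major_px, spec.semi_minor_px, spec.orientation_deg)
    if not mask.any():
        raise UserError("ellipse produced an empty mask")
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    if (mask & border).any():
        raise UserError("ellipse exceeds the image frame")
    rho, _ = _rho_map(mask)
    dapi = np.zeros(image_shape, dtype=float)
    dapi[mask] = spec.base_intensity + (
        spec.peak_intensity - spec.base_intensity
    ) * rho[mask] ** spec.dapi_gradient_exponent
    return mask, ChannelImage(pixels=dapi, pixel_size_um=DEFAULT_PIXEL_SIZE_UM, channel_name="dapi")


def _ray_position(
    rho: np.ndarray,
    mask: np.ndarray,
    center_xy: tuple[float, float],
    psi_deg: float,
    rho_target: float,
) -> tuple[float, float]:
    """Point along the ray at position angle psi where rho ~= rho_target.

    rho increases monotonically outward along any ray of a convex mask, so
    a dense march from the center picks the closest sample.
    """
    h, w = mask.shape
    dx = np.cos(np.radians(psi_deg))
    dy_row = -np.sin(np.radians(psi_deg))
    s = np.arange(0.0, float(max(h, w)) * 1.5, 0.25)
    xs = center_xy[0] + s * dx
    ys = center_xy[1] + s * dy_row
    ix = np.clip(np.round(xs).astype(int), 0, w - 1)
    iy = np.clip(np.round(ys).astype(int), 0, h - 1)
    inside = mask[iy, ix]
    stop = np.argmin(inside) if not inside.all() else len(s)
    if stop == 0:
        raise PlacementError("nucleus centroid outside mask")
    k = int(np.argmin(np.abs(rho[iy[:stop], ix[:stop]] - rho_target)))
    return float(xs[k]), float(ys[k])


MAX_PLACEMENT_ATTEMPTS = 200


def place_territories(
    mask: np.ndarray,
    orientation_deg: float,
    placement: PlacementSpec,
    rng: np.random.Generator,
) -> tuple[list[np.ndarray], np.ndarray, list[dict]]:
    """Place paint territories inside a nucleus mask.

    Returns per-territory boolean masks, the DAPI multiplier field
    (``dapi_contrast`` within territories, 1 elsewhere), and one truth row
    per territory recording the sampled radial position and axial angle as
    well as the realized (post-discretization) values and ring index.
    """
    area_nuc = int(mask.sum())
    rho, _ = _rho_map(mask)
    rows, cols = np.nonzero(mask)
    cx, cy = float(cols.mean()), float(rows.mean())
    radius = np.sqrt(placement.territory_area_fraction * area_nuc / np.pi)
    min_sep = 2.0 * radius + 2.0

    centers: list[tuple[float, float]] = []
    truth: list[dict] = []
    for i in range(placement.n_territories):
        placed = False
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            rho_t = float(np.clip(placement.radial_law.sample(1, rng)[0], 0.0, 1.0))
            theta_t = float(
                sample_axial_angles(1, placement.angular_concentration, rng)[0]
            )
            side = rng.integers(0, 2)  # which end of the axis line
            psi = orientation_deg + theta_t + 180.0 * side
            x, y = _ray_position(rho, mask, (cx, cy), psi, rho_t)
            if all(np.hypot(x - px, y - py) >= min_sep for px, py in centers):
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place territory {i + 1}/{placement.n_territories} "
                f"after {MAX_PLACEMENT_ATTEMPTS} attempts"
            )
        centers.append((x, y))
        tmask = _ellipse_mask(mask.shape, (x, y), radius, radius, 0.0) & mask
        ix, iy = int(round(x)), int(round(y))
        rho_real = float(rho[iy, ix])
        theta_real = (
            axial_angle_deg(
                float(np.degrees(np.arctan2(-(y - cy), x - cx))), orientation_deg
            )
            if (x, y) != (cx, cy)
            else float("nan")
        )
        truth.append(
            {
                "territory": i + 1,
                "centroid_x": x,
                "centroid_y": y,
                "rho_sampled": rho_t,
                "rho": rho_real,
                "theta_sampled_deg": theta_t,
                "theta_deg": theta_real,
                "ring_index": max(1, int(np.ceil(rho_real * 6))),
                "area_px": int(tmask.sum()),
                "dapi_contrast": placement.dapi_contrast,
                "paint_contrast": placement.paint_contrast,
            }
        )
        # stash the mask on the row to avoid a parallel list in callers
        truth[-1]["_mask"] = tmask

    masks = [row.pop("_mask") for row in truth]
    multiplier = np.ones(mask.shape, dtype=float)
    for tmask in masks:
        multiplier[tmask] = placement.dapi_contrast
    return masks, multiplier, truth


def multinucleated_specs(
    n: int,
    gap_px: float,
    base: NucleusSpec,
    image_shape: tuple[int, int],
) -> list[NucleusSpec]:
    """Specs for ``n`` side-by-side nuclei with a given edge-to-edge gap.

    Nuclei are copies of ``base`` rotated major-axis-vertical and spaced
    along x.  A positive gap keeps the masks separable; gap 0 produces
    tangent ellipses whose masks merge under the closing step, emulating
    multinucleated cells or adjacent nuclei that segmentation deliberately
    treats as one object.
    """
    h, w = image_shape
    pitch = 2 * base.semi_minor_px + gap_px
    x0 = (w - 1) / 2 - pitch * (n - 1) / 2
    specs = []
    for i in range(n):
        specs.append(
            base.model_copy(
                update={
                    "center": (x0 + i * pitch, (h - 1) / 2),
                    "orientation_deg": 90.0,
                }
            )
        )
    return specs


@dataclass
class Scene:
    """One rendered two-channel scene with its ground truth."""

    dapi: ChannelImage
    paint: ChannelImage
    nucleus_masks: list[np.ndarray]
    territory_masks: list[list[np.ndarray]]
    nuclei_truth: pd.DataFrame
    territories_truth: pd.DataFrame


def simulate_scene(
    nuclei: list[tuple[NucleusSpec, PlacementSpec]],
    image_shape: tuple[int, int],
    noise: NoiseSpec,
    seed: int | np.random.SeedSequence,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> Scene:
    """Render a scene with one or more nuclei and their territories."""
    rng = np.random.default_rng(seed)
    h, w = image_shape
    dapi = np.full(image_shape, noise.dapi_background, dtype=float)
    paint = np.full(image_shape, noise.paint_background, dtype=float)
    nucleus_masks, all_tmasks = [], []
    nuc_rows, terr_rows = [], []
    for n_idx, (nspec, pspec) in enumerate(nuclei, start=1):
        mask, nuc_dapi = generate_nucleus(nspec, image_shape)
        tmasks, multiplier, truth = place_territories(
            mask, nspec.orientation_deg, pspec, rng
        )
        dapi[mask] = nuc_dapi.pixels[mask] * multiplier[mask]
        union = np.zeros(image_shape, dtype=bool)
        for tmask in tmasks:
            union |= tmask
        paint[union] = noise.paint_background * pspec.paint_contrast
        ecc = np.sqrt(1.0 - (nspec.semi_minor_px / nspec.semi_major_px) ** 2)
        nuc_rows.append(
            {
                "nucleus": n_idx,
                "semi_major_px": nspec.semi_major_px,
                "semi_minor_px": nspec.semi_minor_px,
                "orientation_deg": nspec.orientation_deg,
                "eccentricity": ecc,
                "area_px": int(mask.sum()),
                "n_territories": pspec.n_territories,
                "territory_area_fraction": pspec.territory_area_fraction,
            }
        )
        for row in truth:
            terr_rows.append({"nucleus": n_idx, **row})
        nucleus_masks.append(mask)
        all_tmasks.append(tmasks)
    if noise.sigma > 0:
        dapi = dapi + rng.normal(0.0, noise.sigma, size=dapi.shape)
        paint = paint + rng.normal(0.0, noise.sigma, size=paint.shape)
    dapi = np.clip(dapi, 0.0, None)
    paint = np.clip(paint, 0.0, None)
    return Scene(
        dapi=ChannelImage(dapi, pixel_size_um, "dapi"),
        paint=ChannelImage(paint, pixel_size_um, "paint"),
        nucleus_masks=nucleus_masks,
        territory_masks=all_tmasks,
        nuclei_truth=pd.DataFrame(nuc_rows),
        territories_truth=pd.DataFrame(terr_rows),
    )


class CohortGroup(BaseModel):
    """One experimental condition in a synthetic cohort.

    Nucleus geometry is sampled per scene: the semi-major axis uniformly
    from ``semi_major_px_range``, the axis ratio uniformly from
    ``axis_ratio_range``, the orientation uniformly on [0, 180).
    """

    name: str
    scheme: Literal["normal", "tumor"] = "normal"
    n_scenes: int = Field(default=10, ge=1)
    semi_major_px_range: tuple[float, float] = (44.0, 54.0)
    axis_ratio_range: tuple[float, float] = (1.3, 1.7)
    dapi_gradient_exponent: float = 1.0
    base_intensity: float = 70.0
    peak_intensity: float = 115.0
    placement: PlacementSpec = PlacementSpec()


class CohortSpec(BaseModel):
    """A full synthetic study: groups, frame geometry, and noise model."""

    groups: list[CohortGroup]
    image_shape: tuple[int, int] = (160, 160)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    noise: NoiseSpec = NoiseSpec()


def sample_nucleus_spec(group: CohortGroup, rng: np.random.Generator) -> NucleusSpec:
    a = rng.uniform(*group.semi_major_px_range)
    ratio = rng.uniform(*group.axis_ratio_range)
    return NucleusSpec(
        semi_major_px=a,
        semi_minor_px=a / ratio,
        orientation_deg=float(rng.uniform(0.0, 180.0)),
        dapi_gradient_exponent=group.dapi_gradient_exponent,
        base_intensity=group.base_intensity,
        peak_intensity=group.peak_intensity,
    )


def simulate_cohort_scenes(
    cohort: CohortSpec, seed: int
) -> list[tuple[str, str, Scene]]:
    """Yield (group, scene_id, Scene) for every scene of a cohort, in order."""
    n_total = sum(g.n_scenes for g in cohort.groups)
    seeds = np.random.SeedSequence(seed).spawn(n_total)
    out = []
    i = 0
    for group in cohort.groups:
        for j in range(group.n_scenes):
            rng = np.random.default_rng(seeds[i])
            nspec = sample_nucleus_spec(group, rng)
            scene = simulate_scene(
                [(nspec, group.placement)],
                cohort.image_shape,
                cohort.noise,
                seeds[i],
                pixel_size_um=cohort.pixel_size_um,
            )
            out.append((group.name, f"{group.name}_{j + 1:04d}", scene))
            i += 1
    return out


def generate_cohort(cohort: CohortSpec, out_dir: str | Path, seed: int) -> pd.DataFrame:
    """Write a cohort to disk: one two-channel TIFF per scene + truth CSVs.

    Scenes land in ``out_dir/<group>/<scene>.tif`` as (z=1, c=2, y, x) with
    channel order (dapi, paint); truth tables in ``out_dir``.  Returns the
    territory truth table.  Byte-identical across runs with the same seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nuc_frames, terr_frames = [], []
    for group, scene_id, scene in simulate_cohort_scenes(cohort, seed):
        gdir = out_dir / group
        gdir.mkdir(exist_ok=True)
        stack = np.stack([scene.dapi.pixels, scene.paint.pixels])[np.newaxis]
        tifffile.imwrite(gdir / f"{scene_id}.tif", stack.astype(np.float32))
        for df, acc in (
            (scene.nuclei_truth, nuc_frames),
            (scene.territories_truth, terr_frames),
        ):
            df = df.copy()
            df.insert(0, "scene", scene_id)
            df.insert(0, "group", group)
            acc.append(df)
    nuclei = pd.concat(nuc_frames, ignore_index=True)
    territories = pd.concat(terr_frames, ignore_index=True)
    nuclei.to_csv(out_dir / "nuclei_truth.csv", index=False, float_format="%.17g")
    territories.to_csv(
        out_dir / "territories_truth.csv", index=False, float_format="%.17g"
    )
    return territories
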