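"""End-to-end orchestration: ingest -> segment -> measure -> stats.

A run consumes a directory of two-channel TIFF scenes (immediate
subdirectories are experimental groups; a flat directory is the single
group ``all``), measures every retained nucleus and territory, and emits:

* ``nuclei.csv`` — one row per retained nucleus (morphometry, fragmentation,
  occupancy, ring signal fractions, ring DAPI means raw and normalized);
* ``territories.csv`` — one row per assigned territory (area, centroid,
  axial angle/class, density ratio, modal ring);
* ``stats.csv`` — axial binomial tests per group against the configured
  random-positioning null, per-cell classification tests, pairwise Welch
  tests on occupancy, pairwise Fisher tests on axial counts;
* ``provenance.json`` — version, seed, config, config hash, object
  conservation counters;
* ``run.log`` — every excluded object with a reason code.

Re-running with the same config and seed reproduces every output file
byte-identically (timestamps live only in the log).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .errors import (
    DataError,
    DegeneratePartitionError,
    UndefinedAngleError,
    ZeroSignalError,
)
from .io import (
    NUCLEUS_COLUMNS,
    TERRITORY_COLUMNS,
    max_project,
    read_stack,
    write_measurements,
)
from .metrics import (
    area_occupancy,
    axial_angle,
    classify_cell,
    density_ratio,
    pair_measurements,
)
from .morphometry import fragmentation_score, nucleus_morphometry
from .radial import dapi_ring_intensity, ring_partition, signal_ring_fractions
from .segment import (
    SegmentationLog,
    assign_to_nuclei,
    segment_nuclei,
    segment_territories,
)
from .stats import (
    NAIVE_NULL,
    AxialNull,
    binomial_obs_vs_expected,
    expected_cell_class_probability,
    expected_major_fraction_ellipse,
    expected_major_fraction_mask,
    fisher_exact_2x2,
    welch_t,
)

log = logging.getLogger("territoria")


@dataclass
class PipelineResult:
    nuclei: pd.DataFrame
    territories: pd.DataFrame
    stats: pd.DataFrame
    provenance: dict


def _find_scenes(input_dir: Path) -> list[tuple[str, Path]]:
    scenes = []
    subdirs = sorted(d for d in input_dir.iterdir() if d.is_dir())
    for sub in subdirs:
        for tif in sorted(sub.glob("*.tif")) + sorted(sub.glob("*.tiff")):
            scenes.append((sub.name, tif))
    if not scenes:
        for tif in sorted(input_dir.glob("*.tif")) + sorted(input_dir.glob("*.tiff")):
            scenes.append(("all", tif))
    if not scenes:
        raise DataError(f"no scenes found under {input_dir}")
    return scenes


def measure_scene(
    group: str, scene_id: str, dapi, paint, config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Measure one projected scene; returns nucleus rows, territory rows, counters."""
    params = config.segmentation.to_params()
    seglog = SegmentationLog()
    nuclei = segment_nuclei(dapi, params, log=seglog)
    n_excluded = {reason: 0 for reason in ("TOO_LARGE", "BORDER", "TOO_SMALL")}
    for lab, area, reason in seglog.excluded:
        n_excluded[reason] += 1
        log.info("%s: nucleus component %d (area %d) excluded: %s", scene_id, lab, area, reason)
    counters = {
        "nuclei_detected": len(nuclei) + len(seglog.excluded),
        "nuclei_retained": len(nuclei),
        **{f"nuclei_excluded_{k.lower()}": v for k, v in n_excluded.items()},
    }
    territories = []
    if nuclei:
        terrlog = SegmentationLog()
        territories = segment_territories(paint, params, nuclei=nuclei, log=terrlog)
        for lab, area, reason in terrlog.excluded:
            log.info("%s: territory component %d (area %d) excluded: %s", scene_id, lab, area, reason)
        assign_to_nuclei(territories, nuclei)
        for t in territories:
            if t.unassigned:
                log.info("%s: territory %d unassigned; excluded", scene_id, t.label)

    nuc_rows, terr_rows = [], []
    for nuc in nuclei:
        shape = nucleus_morphometry(nuc, config.pixel_size_um)
        mine = [t for t in territories if not t.unassigned and t.parent_nucleus == nuc.label]
        frag = fragmentation_score(territories, nuc.label)
        ringmap = ring_partition(nuc, config.rings.n_rings, config.rings.mode)
        row = {
            "scene": scene_id,
            "group": group,
            "nucleus": nuc.label,
            "area_px": nuc.area_px,
            "area_um2": shape.area_um2,
            "major_um": shape.major_axis_um,
            "minor_um": shape.minor_axis_um,
            "eccentricity": shape.eccentricity,
            "orientation_deg": shape.orientation_deg,
            "centroid_x": shape.centroid_xy[0],
            "centroid_y": shape.centroid_xy[1],
            "fragmentation_score": frag.score,
            "fragmentation_class": frag.dichotomy,
            "occupancy_fraction": area_occupancy(mine, nuc),
        }
        if frag.score == 0:
            log.info("%s: nucleus %d has no territories; excluded from axial/occupancy stats", scene_id, nuc.label)
        union = np.zeros(nuc.pixels.shape, dtype=bool)
        for t in mine:
            union |= t.pixels
        try:
            profile = signal_ring_fractions(paint, ringmap, restrict=union if mine else None)
            for k, frac in enumerate(profile.fractions, start=1):
                row[f"ring{k}_fraction"] = frac
        except ZeroSignalError:
            log.info("%s: nucleus %d zero paint signal; profile undefined", scene_id, nuc.label)
            for k in range(1, config.rings.n_rings + 1):
                row[f"ring{k}_fraction"] = np.nan
        try:
            intensity = dapi_ring_intensity(dapi, ringmap)
            for k in range(config.rings.n_rings):
                row[f"ring{k + 1}_dapi"] = intensity.means[k]
                row[f"ring{k + 1}_dapi_norm"] = intensity.normalized[k]
        except DegeneratePartitionError:
            log.info("%s: nucleus %d too small for a full ring partition", scene_id, nuc.label)
        row["inter_distance_um"] = row["inter_angle_deg"] = np.nan
        axial_measurements = []
        for t in mine:
            trow = {
                "scene": scene_id,
                "group": group,
                "nucleus": nuc.label,
                "territory": t.label,
                "area_px": t.area_px,
                "centroid_x": t.centroid_xy[0],
                "centroid_y": t.centroid_xy[1],
                "r_fragment": density_ratio(dapi, t, nuc).r_fragment,
            }
            try:
                ax = axial_angle(t.centroid_xy, shape)
                trow["theta_deg"] = ax.theta_deg
                trow["axial_class"] = ax.axial_class
                axial_measurements.append(ax)
            except UndefinedAngleError:
                log.info("%s: territory %d angle undefined; excluded from axial stats", scene_id, t.label)
                trow["theta_deg"] = np.nan
                trow["axial_class"] = ""
            try:
                tprofile = signal_ring_fractions(paint, ringmap, restrict=t.pixels)
                trow["ring_index"] = int(np.argmax(tprofile.fractions)) + 1
            except ZeroSignalError:
                trow["ring_index"] = 0
            terr_rows.append(trow)
        if len(mine) == 2:
            try:
                dist, ang = pair_measurements(mine, shape, config.pixel_size_um)
                row["inter_distance_um"], row["inter_angle_deg"] = dist, ang
            except UndefinedAngleError:
                log.info("%s: nucleus %d pair angle undefined", scene_id, nuc.label)
        scheme = config.scheme_for(group)
        row["cell_axial_class"] = ""
        if axial_measurements and (scheme == "tumor" or len(axial_measurements) == 2):
            row["cell_axial_class"] = classify_cell(axial_measurements, scheme).label
        nuc_rows.append(row)
    return pd.DataFrame(nuc_rows), pd.DataFrame(terr_rows), counters


def _null_for_group(config: RunConfig, group_nuclei: pd.DataFrame, masks, seed: int):
    model = config.null_model.model
    if model == "naive":
        return NAIVE_NULL
    if model == "ellipse_corrected":
        ratio = (group_nuclei["major_um"] / group_nuclei["minor_um"]).mean()
        return expected_major_fraction_ellipse(float(ratio), 1.0)
    if not masks:
        return NAIVE_NULL
    rng = np.random.default_rng(seed)
    estimates = [
        expected_major_fraction_mask(mask, shape, config.null_model.n_mc, rng).p_major
        for mask, shape in masks
    ]
    return AxialNull(p_major=float(np.mean(estimates)), model="empirical_mask")


def compute_stats(
    nuclei: pd.DataFrame,
    territories: pd.DataFrame,
    config: RunConfig,
    group_masks: dict | None = None,
) -> pd.DataFrame:
    """Group-level statistics from the measurement tables."""
    rows = []
    groups = sorted(nuclei["group"].unique()) if len(nuclei) else []
    for group in groups:
        gnuc = nuclei[(nuclei["group"] == group) & (nuclei["fragmentation_score"] > 0)]
        gterr = territories[
            (territories["group"] == group) & (territories["axial_class"] != "")
        ].dropna(subset=["theta_deg"])
        if not len(gterr):
            continue
        null = _null_for_group(
            config, gnuc, (group_masks or {}).get(group, []), config.seed
        )
        k = int((gterr["axial_class"] == "major_parallel").sum())
        n = int(len(gterr))
        res = binomial_obs_vs_expected(k, n, null.p_major)
        rows.append(
            {
                "test": "axial_binomial_per_chromosome",
                "groups": group,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n": n,
                "detail": f"k={k} p0={null.p_major:.6f} model={null.model}",
            }
        )
        scheme = config.scheme_for(group)
        classed = gnuc[gnuc["cell_axial_class"] != ""]
        if len(classed):
            if scheme == "normal":
                k_cell = int((classed["cell_axial_class"] == "both_minor").sum())
                p_cell = float((1.0 - null.p_major) ** 2)
                label = "both_minor"
            else:
                k_cell = int((classed["cell_axial_class"] == "ge50_major").sum())
                per_cell = [
                    expected_cell_class_probability(null.p_major, "tumor", int(s))
                    for s in classed["fragmentation_score"]
                ]
                p_cell = float(np.mean(per_cell))
                label = "ge50_major"
            res = binomial_obs_vs_expected(k_cell, len(classed), p_cell)
            rows.append(
                {
                    "test": "axial_binomial_per_cell",
                    "groups": group,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "n": len(classed),
                    "detail": f"k={k_cell} class={label} p0={p_cell:.6f}",
                }
            )
    for ga, gb in itertools.combinations(groups, 2):
        occ_a = nuclei.query("group == @ga and fragmentation_score > 0")["occupancy_fraction"]
        occ_b = nuclei.query("group == @gb and fragmentation_score > 0")["occupancy_fraction"]
        if len(occ_a) >= 2 and len(occ_b) >= 2:
            res = welch_t(occ_a.to_numpy(), occ_b.to_numpy())
            rows.append(
                {
                    "test": "occupancy_welch_t",
                    "groups": f"{ga}|{gb}",
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "n": res.n,
                    "detail": "",
                }
            )
        ta = territories[(territories["group"] == ga) & (territories["axial_class"] != "")]
        tb = territories[(territories["group"] == gb) & (territories["axial_class"] != "")]
        if len(ta) and len(tb):
            table = np.array(
                [
                    [(ta["axial_class"] == "major_parallel").sum(), (ta["axial_class"] == "minor_parallel").sum()],
                    [(tb["axial_class"] == "major_parallel").sum(), (tb["axial_class"] == "minor_parallel").sum()],
                ]
            )
            res = fisher_exact_2x2(table)
            rows.append(
                {
                    "test": "axial_fisher_exact",
                    "groups": f"{ga}|{gb}",
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "n": res.n,
                    "detail": "",
                }
            )
    return pd.DataFrame(
        rows, columns=["test", "groups", "statistic", "p_value", "n", "detail"]
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis over a directory of scenes."""
    input_dir = Path(config.input_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        scenes = _find_scenes(input_dir)
        nuc_frames, terr_frames = [], []
        totals: dict[str, int] = {}
        channel_map = {"dapi": config.channels.dapi, "paint": config.channels.paint}
        for group, path in scenes:
            try:
                stack = read_stack(path, channel_map, config.pixel_size_um, config.axes)
                dapi = max_project(stack, "dapi")
                paint = max_project(stack, "paint")
                nuc_df, terr_df, counters = measure_scene(
                    group, path.stem, dapi, paint, config
                )
            except DataError as exc:
                log.warning("scene %s failed: %s", path, exc)
                continue
            for key, val in counters.items():
                totals[key] = totals.get(key, 0) + val
            if len(nuc_df):
                nuc_frames.append(nuc_df)
            if len(terr_df):
                terr_frames.append(terr_df)
        nuclei = (
            pd.concat(nuc_frames, ignore_index=True)
            if nuc_frames
            else pd.DataFrame(columns=NUCLEUS_COLUMNS)
        )
        territories = (
            pd.concat(terr_frames, ignore_index=True)
            if terr_frames
            else pd.DataFrame(columns=TERRITORY_COLUMNS)
        )
        stats = compute_stats(nuclei, territories, config)
        write_measurements(nuclei, out_dir / "nuclei.csv", NUCLEUS_COLUMNS)
        write_measurements(territories, out_dir / "territories.csv", TERRITORY_COLUMNS)
        stats.to_csv(out_dir / "stats.csv", index=False, float_format="%.17g")
        provenance = {
            "version": __version__,
            "seed": config.seed,
            "config": config.model_dump(mode="json"),
            "config_hash": config.config_hash(),
            "n_scenes": len(scenes),
            "counts": totals,
        }
        with open(out_dir / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)
        return PipelineResult(
            nuclei=nuclei, territories=territories, stats=stats, provenance=provenance
        )
    finally:
        log.removeHandler(handler)
        handler.close()
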