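"""Run configuration: validated before any computation, serialized verbatim
into the run's provenance record."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, ValidationError

from .errors import UserError
from .segment import SegmentationParams
from .synth import DEFAULT_PIXEL_SIZE_UM, CohortSpec


class ChannelsConfig(BaseModel):
    dapi: int = 0
    paint: int = 1


class SegmentationConfig(BaseModel):
    nlm_patch_size: int = 3
    nlm_patch_distance: int = 7
    nlm_h: float | None = None
    closing_radius: int = 2
    median_radius: int = 2
    n_bins: int = 256
    nucleus_max_area_px: int = 10_000
    nucleus_min_area_px: int | None = 500
    territory_min_area_px: int = 100
    territory_max_area_px: int = 10_000

    def to_params(self) -> SegmentationParams:
        return SegmentationParams(**self.model_dump())


class RingConfig(BaseModel):
    n_rings: int = Field(default=6, ge=1)
    mode: Literal["equal_width", "equal_area"] = "equal_width"


class NullConfig(BaseModel):
    model: Literal["naive", "ellipse_corrected", "empirical_mask"] = "naive"
    n_mc: int = Field(default=10_000, ge=100)


class RunConfig(BaseModel):
    """Everything a pipeline run needs; see docs/methods.md for semantics."""

    input_dir: Path
    out_dir: Path
    pixel_size_um: float = Field(default=DEFAULT_PIXEL_SIZE_UM, gt=0)
    axes: str = "zcyx"
    channels: ChannelsConfig = ChannelsConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    rings: RingConfig = RingConfig()
    null_model: NullConfig = NullConfig()
    schemes: dict[str, Literal["normal", "tumor"]] = {}  # group -> scheme
    seed: int = 0

    def scheme_for(self, group: str) -> Literal["normal", "tumor"]:
        return self.schemes.get(group, "normal")

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_run_config(path: str | Path) -> RunConfig:
    return _load(path, RunConfig)


def load_cohort_spec(path: str | Path) -> CohortSpec:
    return _load(path, CohortSpec)


def _load(path: str | Path, model: type[BaseModel]):
    path = Path(path)
    if not path.exists():
        raise UserError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return model.model_validate(raw)
    except ValidationError as exc:
        raise UserError(f"invalid config {path}: {exc}") from exc
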