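"""Pipeline configuration: one validated, hashable document for every stage.

All tunables of the analysis live here so that a result file can echo the
exact configuration (plus its hash and the global seed) that produced it.
Validation happens on load with field-level messages; unknown keys are
rejected rather than ignored.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigError

SCHEMA_VERSION = 1


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SegmentationConfig(_Strict):
    alpha: float = 0.1
    beta: float = 0.05
    mu: float = Field(0.2, gt=0)
    kappa: float = Field(5.0, gt=0)
    gvf_iterations: int = Field(80, ge=1)
    snake_iterations: int = Field(300, ge=1)
    tol: float = Field(0.1, gt=0)
    step: float = Field(1.0, gt=0)
    n_vertices: int = Field(120, ge=8)
    smooth_sigma: float = Field(2.0, ge=0)
    center: Optional[tuple[float, float]] = None  # None = auto-estimate


class ExclusionConfig(_Strict):
    dark_threshold: float = Field(30.0, ge=0, le=100)
    bright_threshold: float = Field(85.0, ge=0, le=100)
    # whether thresholds are interpreted on color-corrected or raw L*
    apply_to: Literal["corrected", "raw"] = "corrected"


class CheckerPatchConfig(_Strict):
    patch_id: str
    role: Literal["achromatic", "chromatic"]
    rectangle: tuple[int, int, int, int]  # (row0, col0, height, width)
    reference: tuple[float, float, float]  # (L, a, b)


class CorrectionConfig(_Strict):
    enabled: bool = True
    cross_channel: bool = False
    patches: list[CheckerPatchConfig] = Field(default_factory=list)


class TDCHConfig(_Strict):
    L_lower: tuple[float, ...] = (30.0, 35.0, 40.0, 45.0)
    L_width: float = Field(5.0, gt=0)
    a_lower: tuple[float, ...] = (6.0, 12.0, 18.0, 24.0)
    a_width: float = Field(6.0, gt=0)
    mapping: dict[str, tuple[float, float]] | None = None  # None = default V1..V7
    pre_exclusion_denominator: bool = False


class StatsConfig(_Strict):
    route_by_normality: bool = True
    normality_alpha: float = Field(0.05, gt=0, lt=1)
    lilliefors_mc: int = Field(10_000, ge=100)
    adjust: Optional[Literal["bonferroni", "fdr_bh"]] = None


class ClassifyConfig(_Strict):
    methods: tuple[str, ...] = ("naive_bayes", "knn", "svm")
    k: int = Field(5, ge=1)
    kernel: str = "rbf"
    cost: float = Field(1.0, gt=0)
    folds: int = Field(10, ge=2)


class PipelineConfig(_Strict):
    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    log_level: Literal["debug", "info", "warning", "error"] = "info"
    white_point: Literal["D65"] = "D65"
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    exclusion: ExclusionConfig = Field(default_factory=ExclusionConfig)
    correction: CorrectionConfig = Field(default_factory=CorrectionConfig)
    tdch: TDCHConfig = Field(default_factory=TDCHConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    classify: ClassifyConfig = Field(default_factory=ClassifyConfig)

    def hash(self) -> str:
        doc = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived from the global seed and the stage name."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def load_config(path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        msgs = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ConfigError(f"invalid configuration: {msgs}") from exc
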