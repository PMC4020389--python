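"""End-to-end wiring: image(s) -> segmentation -> correction -> exclusion
-> TDCH -> cohort CSV, plus the stats and classification entry points.

Each image is processed independently; a failure (unreadable file, failed
segmentation) is logged and skipped so a batch run always completes.  Every
result file embeds the configuration hash and the global seed, making two
runs with the same config and seed byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .classify import ClassifierSpec, cv_accuracy
from .colorspace import read_rgb, srgb_to_lab
from .config import PipelineConfig
from .correction import CorrectionModel, apply_correction, fit_correction, sample_checker
from .errors import TongueLabError
from .exclusion import ExclusionParams, valid_pixel_mask
from .segmentation import SnakeParams, TongueMask, segment_tongue
from .stats import format_table, group_compare
from .tdch import TDCHGrid, VariableMapping, compute_histogram, extract_variables, v_ratio

logger = logging.getLogger("tonguelab")

COHORT_COLUMNS = ["subject_id", "visit", "group"] + [f"V{i}" for i in range(1, 8)] + ["VR"]


def _snake_params(config: PipelineConfig) -> SnakeParams:
    s = config.segmentation
    return SnakeParams(
        alpha=s.alpha, beta=s.beta, mu=s.mu, kappa=s.kappa,
        gvf_iterations=s.gvf_iterations, snake_iterations=s.snake_iterations,
        tol=s.tol, step=s.step, n_vertices=s.n_vertices,
        smooth_sigma=s.smooth_sigma, center=s.center,
    )


def _grid(config: PipelineConfig) -> TDCHGrid:
    t = config.tdch
    return TDCHGrid(
        L_lower=t.L_lower, L_width=t.L_width, a_lower=t.a_lower, a_width=t.a_width
    )


def _mapping(config: PipelineConfig) -> VariableMapping:
    if config.tdch.mapping is None:
        return VariableMapping()
    return VariableMapping(bins={k: tuple(v) for k, v in config.tdch.mapping.items()})


def analyze_image(
    rgb: np.ndarray,
    config: PipelineConfig,
    manual_mask: np.ndarray | None = None,
) -> dict:
    """Run the full single-image analysis; returns the result document."""
    lab_raw = srgb_to_lab(rgb)
    if manual_mask is not None:
        tongue = TongueMask(mask=manual_mask, provenance="manual")
    else:
        tongue = segment_tongue(lab_raw, _snake_params(config))

    if config.correction.enabled and config.correction.patches:
        patches = config.correction.patches
        checker = sample_checker(
            lab_raw,
            [tuple(p.rectangle) for p in patches],
            [tuple(p.reference) for p in patches],
            [p.role for p in patches],
            [p.patch_id for p in patches],
        )
        model = fit_correction(checker, cross_channel=config.correction.cross_channel)
        for msg in model.warn_if_implausible():
            logger.warning("correction: %s", msg)
    else:
        model = CorrectionModel.identity()
    lab_corrected, n_clipped = apply_correction(lab_raw, model, return_clip_count=True)

    excl_params = ExclusionParams(
        dark_threshold=config.exclusion.dark_threshold,
        bright_threshold=config.exclusion.bright_threshold,
    )
    lab_for_exclusion = lab_corrected if config.exclusion.apply_to == "corrected" else lab_raw
    valid, report = valid_pixel_mask(lab_for_exclusion, tongue, excl_params)

    grid = _grid(config)
    denominator = tongue.n_pixels if config.tdch.pre_exclusion_denominator else None
    hist = compute_histogram(lab_corrected, valid, grid, denominator=denominator)
    variables = extract_variables(hist, _mapping(config))
    vr = v_ratio(variables["V3"], variables["V7"])
    return {
        "provenance": tongue.provenance,
        "n_tongue": tongue.n_pixels,
        "exclusion": report.as_dict(),
        "correction": model.as_dict(),
        "correction_clipped": n_clipped,
        "histogram": {
            f"L{Lo:g}_a{ao:g}": {"count": c, "proportion": c / hist.denominator}
            for (Lo, ao), c in hist.counts.items()
        },
        "denominator": hist.denominator,
        "variables": variables,
        "VR": vr,
        "mapping_is_default": config.tdch.mapping is None,
    }


def run_analyze(
    image_paths,
    config: PipelineConfig,
    out_dir=None,
    *,
    groups: dict[str, str] | None = None,
    manual_masks: dict[str, object] | None = None,
) -> pd.DataFrame:
    """Analyze a batch of images and assemble the cohort table.

    ``groups`` maps image stem -> group label (default "unknown");
    ``manual_masks`` maps image stem -> mask PNG path.  Per-image JSON results
    and the cohort CSV are written when ``out_dir`` is given.  Unreadable or
    unsegmentable images are skipped with a logged error.
    """
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for path in image_paths:
        stem = Path(path).stem
        try:
            rgb = read_rgb(path)
            mask = None
            if manual_masks and stem in manual_masks:
                mask = tio.read_mask(manual_masks[stem])
            result = analyze_image(rgb, config, manual_mask=mask)
        except (TongueLabError, OSError) as exc:
            logger.error("skipping %s: %s", path, exc)
            continue
        row = {
            "subject_id": stem,
            "visit": "first",
            "group": (groups or {}).get(stem, "unknown"),
            **result["variables"],
            "VR": result["VR"],
        }
        rows.append(row)
        if out_dir is not None:
            tio.write_result_json(
                out_dir / f"{stem}.json", result,
                config_hash=config.hash(), seed=config.seed,
            )
    cohort = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    if out_dir is not None:
        cohort.to_csv(out_dir / "cohort.csv", index=False, float_format="%.10g")
    return cohort


def run_stats(cohort: pd.DataFrame, config: PipelineConfig, *, paired: bool = False):
    """Group (or paired-visit) comparison of V1..V7 plus VR where defined."""
    s = config.stats
    variables = [f"V{i}" for i in range(1, 8)]
    table = group_compare(
        cohort, variables, paired=paired,
        route_by_normality=s.route_by_normality,
        normality_alpha=s.normality_alpha,
        lilliefors_mc=s.lilliefors_mc,
        adjust=s.adjust,
    )
    return table


def run_classify(cohort: pd.DataFrame, config: PipelineConfig) -> dict:
    c = config.classify
    out = {}
    for method in c.methods:
        spec = ClassifierSpec(
            method=method, k=c.k, kernel=c.kernel, cost=c.cost,
            folds=c.folds, seed=config.stage_seed("classify"),
        )
        out[method] = cv_accuracy(cohort, spec).as_dict()
    return out


__all__ = [
    "analyze_image",
    "run_analyze",
    "run_stats",
    "run_classify",
    "format_table",
    "COHORT_COLUMNS",
]
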