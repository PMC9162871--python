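"""End-to-end orchestration: simulate -> extract -> train/evaluate.

Everything here is a thin composition of the other modules so the same code
path serves the CLI, the test suite and scripted experiments. All
randomness flows from one root seed through named substreams.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.color import rgb2gray

from . import model as modeling
from .errors import DataError
from .preprocess import (
    RoiMask,
    Volume,
    discretize,
    log_filter,
    normalize_intensities,
    register_mask_to_reference,
    register_to_reference,
    resample_nearest,
)
from .stain import StainModel, separate_stains, simulate_single_stain
from .synth import CohortRecord, SynthParams, apply_exclusions, generate_cohort, simulate_he_tile, simulate_mri_case
from .texture import (
    OFFSETS_2D_4,
    OFFSETS_3D_13,
    aggregate_features,
    compute_glcm,
    haralick,
    shape_features,
)

__all__ = ["PipelineConfig", "ExperimentResult", "extract_mri_features",
           "extract_pathology_features", "build_feature_tables", "train_evaluate",
           "run_experiment"]

log = logging.getLogger("texstack")


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the extraction and modeling stages, with defaults."""

    target_spacing_mm: tuple[float, float, float] = (2.5, 1.25, 1.25)
    gray_levels: int = 32
    log_sigmas_mm: tuple[float, ...] = (1.0,)
    include_unfiltered: bool = True
    tile_gray_levels: int = 32
    test_fraction: float = 35.0 / 114.0
    alpha: float = 0.05
    top_k: int = 8
    tie_tolerance: float = 0.02
    bootstrap_reps: int = 2000
    algorithms: tuple[str, ...] = modeling.ALGORITHMS

    def as_dict(self) -> dict:
        return {
            "target_spacing_mm": list(self.target_spacing_mm),
            "gray_levels": self.gray_levels,
            "log_sigmas_mm": list(self.log_sigmas_mm),
            "include_unfiltered": self.include_unfiltered,
            "tile_gray_levels": self.tile_gray_levels,
            "test_fraction": self.test_fraction,
            "alpha": self.alpha,
            "top_k": self.top_k,
            "tie_tolerance": self.tie_tolerance,
            "bootstrap_reps": self.bootstrap_reps,
            "algorithms": list(self.algorithms),
        }


def _texture_row(volume: Volume, mask: RoiMask, config: PipelineConfig, prefix: str) -> dict[str, float]:
    roi = discretize(volume, mask, config.gray_levels)
    glcms = compute_glcm(roi, OFFSETS_3D_13, symmetric=True, normalize=True)
    feats = aggregate_features([haralick(g) for g in glcms if not g.empty])
    return {f"{prefix}{k}": v for k, v in feats.as_dict().items()}


def extract_mri_features(
    volumes: dict[str, Volume], mask: RoiMask, config: PipelineConfig
) -> dict[str, dict[str, float]]:
    """Per-sequence texture + shape features on a common resampled grid.

    The ROI (drawn on DWI) defines the reference grid: the DWI volume is
    resampled to the target spacing, the other sequences are registered to
    that grid by spatial location, intensities are standardized over the
    ROI, and co-occurrence features are computed from the unfiltered and
    Laplacian-of-Gaussian-filtered images. Shape descriptors come from the
    registered mask.
    """
    reference = resample_nearest(volumes["DWI"], config.target_spacing_mm)
    common_mask = register_mask_to_reference(mask, reference)
    rows: dict[str, dict[str, float]] = {}
    shape_row = {
        f"shape_{k}": v for k, v in shape_features(common_mask).as_dict().items()
    }
    for seq, vol in volumes.items():
        on_grid = register_to_reference(vol, reference, fill_value=float(vol.data.min()))
        standardized = normalize_intensities(on_grid, common_mask)
        row: dict[str, float] = {}
        if config.include_unfiltered:
            row.update(_texture_row(standardized, common_mask, config, "glcm_"))
        for sigma in config.log_sigmas_mm:
            filtered = log_filter(standardized, sigma)
            row.update(_texture_row(filtered, common_mask, config, f"log{sigma:g}_glcm_"))
        row.update(shape_row)
        rows[seq] = row
    return rows


def _tile_texture(gray: np.ndarray, levels: int) -> dict[str, float]:
    lo, hi = float(gray.min()), float(gray.max())
    if hi == lo:
        levels_img = np.ones(gray.shape, dtype=np.int32)
    else:
        binned = np.floor((gray - lo) / (hi - lo) * levels).astype(np.int32)
        levels_img = np.minimum(binned, levels - 1) + 1
    glcms = compute_glcm(levels_img, OFFSETS_2D_4, symmetric=True, normalize=True, levels=levels)
    feats = aggregate_features([haralick(g) for g in glcms if not g.empty])
    return {f"glcm_{k}": v for k, v in feats.as_dict().items()}


def extract_pathology_features(
    tile: np.ndarray, config: PipelineConfig, model: StainModel | None = None
) -> dict[str, dict[str, float]]:
    """Six co-occurrence features per simulated single-stain image.

    The RGB tile is separated into hematoxylin and eosin concentrations,
    each re-rendered as a single-stain image, converted to grayscale and
    discretized before the 2D GLCM (four distance-1 directions, averaged).
    """
    model = model or StainModel.reference_he()
    maps = separate_stains(tile, model)
    rows = {}
    for which in ("hematoxylin", "eosin"):
        single = simulate_single_stain(maps, which, model)
        gray = rgb2gray(single)
        rows[which] = _tile_texture(gray, config.tile_gray_levels)
    return rows


def build_feature_tables(
    records: list[CohortRecord],
    params: SynthParams,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Long feature table: one row per (usable patient, source)."""
    usable = apply_exclusions(records)
    if not usable:
        raise DataError("no usable patients after exclusions")
    rows = []
    for rec in usable:
        volumes, mask = simulate_mri_case(rec, params)
        per_seq = extract_mri_features(volumes, mask, config)
        tile = simulate_he_tile(rec, params)
        per_stain = extract_pathology_features(tile, config)
        for source, feats in {**per_seq, **per_stain}.items():
            rows.append(
                {"patient_id": rec.patient_id, "source": source, "label": rec.label, **feats}
            )
    table = pd.DataFrame(rows)
    log.info("feature table: %d rows, %d patients", len(table), len(usable))
    return table


@dataclass
class ExperimentResult:
    records: list[CohortRecord]
    table: pd.DataFrame
    weak_results: list[modeling.WeakResult]
    best_mri: modeling.WeakResult
    best_stain: modeling.WeakResult
    stacked: modeling.StackedModel
    report: modeling.EvalReport
    config: PipelineConfig = field(default_factory=PipelineConfig)

    def weak_summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": r.source,
                    "algorithm": r.algorithm,
                    "auc_train": r.auc_train,
                    "auc_test": r.auc_test,
                    **{f"test_{k}": v for k, v in r.metrics_test.items()},
                }
                for r in self.weak_results
            ]
        )


def train_evaluate(
    table: pd.DataFrame, config: PipelineConfig, seed: int = 0
) -> tuple[list[modeling.WeakResult], modeling.WeakResult, modeling.WeakResult, modeling.StackedModel, modeling.EvalReport]:
    """Train all source x algorithm weak models, select, stack, evaluate."""
    sources = sorted(table["source"].unique())
    mri_sources = [s for s in sources if s in modeling.MRI_SOURCES]
    stain_sources = [s for s in sources if s in modeling.STAIN_SOURCES]
    if not mri_sources or not stain_sources:
        raise DataError(
            f"stacking needs both modalities; found MRI={mri_sources}, stain={stain_sources}"
        )
    weak_results = []
    per_source_best = {}
    for source in sources:
        candidates = [
            modeling.train_weak(
                table, source, alg, seed=seed, alpha=config.alpha, top_k=config.top_k
            )
            for alg in config.algorithms
        ]
        weak_results.extend(candidates)
        per_source_best[source] = modeling.select_best_weak(
            candidates, tie_tolerance=config.tie_tolerance
        )
        log.info(
            "%s: best weak = %s (test AUC %.3f)",
            source,
            per_source_best[source].algorithm,
            per_source_best[source].auc_test,
        )
    best_mri = modeling.select_best_weak(
        [per_source_best[s] for s in mri_sources], tie_tolerance=config.tie_tolerance
    )
    best_stain = modeling.select_best_weak(
        [per_source_best[s] for s in stain_sources], tie_tolerance=config.tie_tolerance
    )
    stacked, report = modeling.stack_and_evaluate(
        best_mri, best_stain, seed=seed, bootstrap_reps=config.bootstrap_reps
    )
    return weak_results, best_mri, best_stain, stacked, report


def run_experiment(
    params: SynthParams, config: PipelineConfig | None = None, seed: int | None = None
) -> ExperimentResult:
    """The full pipeline on a synthetic cohort.

    ``seed`` overrides ``params.seed`` and also drives the split and every
    stochastic model component.
    """
    config = config or PipelineConfig()
    if seed is not None:
        params = SynthParams(**{**params.__dict__, "seed": seed})
    root_seed = params.seed
    records = generate_cohort(params)
    usable = apply_exclusions(records)
    labels = [r.label for r in usable]
    assignment = modeling.split_cohort(
        [r.patient_id for r in usable],
        labels,
        test_fraction=config.test_fraction,
        stratify=True,
        seed=root_seed,
    )
    records = [
        (
            CohortRecord(**{**r.__dict__, "split": assignment[r.patient_id]})
            if r.patient_id in assignment
            else r
        )
        for r in records
    ]
    table = build_feature_tables(records, params, config)
    table["split"] = table["patient_id"].map(assignment)
    weak_results, best_mri, best_stain, stacked, report = train_evaluate(
        table, config, seed=root_seed
    )
    return ExperimentResult(
        records=records,
        table=table,
        weak_results=weak_results,
        best_mri=best_mri,
        best_stain=best_stain,
        stacked=stacked,
        report=report,
        config=config,
    )
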