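"""End-to-end experiment orchestration.

Two experiments mirror the study design:

1. *Single-CR robustness*: for each compression ratio in the grid, train
   the classifier on images at that CR (five-fold cross-validation) and
   test at the same CR — the diagonal of the generalization matrix.
2. *Cross-CR generalization and augmentation*: the full train-CR x
   test-CR matrix, plus models trained on nested mixtures of CRs
   (CR1, CR1+next, ..., all CRs) evaluated on every single CR, probing
   compression as data augmentation.

The clinical-scale grid has eleven conditions (1, 15, 20, 25, 50, 100,
500, 1K, 5K, 10K, 11K). On desk-scale synthetic images the codestream
floor caps the reachable CR well below 10K, so the desk grid keeps the
low conditions and substitutes the two largest reachable values as the
"extreme" conditions; the mapping is recorded in the run provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import codec, evaluation, synthdata
from .cnn3 import ModelConfig, TrainConfig

logger = logging.getLogger(__name__)

#: the clinical-scale grid: eleven CR conditions
CLINICAL_CR_GRID = [1, 15, 20, 25, 50, 100, 500, 1000, 5000, 10000, 11000]

#: published subject counts of the clinical cohort this pipeline emulates;
#: the binary task groups normal+benign against malignant (~4:1)
CLINICAL_COHORT_COUNTS = {"normal": 5672, "benign": 1686, "malignant": 1753}


def nonmalignant_group_size(counts: dict = CLINICAL_COHORT_COUNTS) -> int:
    """Size of the non-malignant arm of the binary task."""
    return counts["normal"] + counts["benign"]


def desk_extreme_crs(sample_pixels: np.ndarray,
                     fractions=(0.5, 0.95)) -> list[int]:
    """The scaled-down 'extreme' conditions: fractions of the largest CR
    the encoder can reach for this image size and content."""
    max_cr = codec.probe_max_cr(sample_pixels)
    return [int(round(f * max_cr)) for f in fractions]


def desk_cr_grid(sample_pixels: np.ndarray,
                 low_crs=(1, 15, 50, 100)) -> list[int]:
    """Low conditions plus the two largest reachable extremes."""
    return sorted(set(list(low_crs) + desk_extreme_crs(sample_pixels)))


@dataclass
class ExperimentConfig:
    n_subjects: int = 400
    seed: int = 0
    width: int = 256
    height: int = 320
    separability: float = 0.8
    class_weights: tuple = (0.62, 0.18, 0.20)
    cr_grid: list | str = "desk"   # "desk", "clinical", or explicit list
    k_folds: int = 5
    split_ratio: tuple = (7, 1, 2)
    resize_factor: float = 0.3
    rate_tolerance: float = 0.10
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self):
        if isinstance(self.cr_grid, (list, tuple)):
            grid = sorted(self.cr_grid)
            if grid != sorted(set(grid)) or (np.asarray(grid) < 1).any():
                raise ValueError("cr_grid must be unique values >= 1")
        if not 0 < self.resize_factor <= 1:
            raise ValueError("resize_factor must lie in (0, 1]")

    def resolve_grid(self, sample_pixels=None) -> list:
        if self.cr_grid == "clinical":
            return list(CLINICAL_CR_GRID)
        if self.cr_grid == "desk":
            if sample_pixels is None:
                raise ValueError("desk grid needs a sample image to probe")
            return desk_cr_grid(sample_pixels)
        return sorted(self.cr_grid)

    @classmethod
    def from_yaml(cls, path):
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        model = ModelConfig(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in raw.pop("model", {}).items()})
        train = TrainConfig(**raw.pop("train", {}))
        return cls(model=model, train=train, **raw)


@dataclass
class ExperimentContext:
    """Everything the experiments share: cohort, materialized datasets,
    the resolved CR grid and the fold split."""

    config: ExperimentConfig
    studies: list
    manifest: pd.DataFrame
    cr_grid: list
    datasets: dict
    compression_stats: list
    split: evaluation.FoldSplit


def prepare(config: ExperimentConfig) -> ExperimentContext:
    """Generate the cohort, resolve the grid, compress and preprocess."""
    studies, manifest = synthdata.generate_cohort(
        config.seed, config.n_subjects, config.class_weights,
        config.width, config.height, config.separability)
    grid = config.resolve_grid(studies[0].views["LCC"].pixels)
    logger.info("resolved CR grid: %s", grid)
    rc = codec.RateControlConfig(tolerance=config.rate_tolerance)
    datasets, stats = evaluation.materialize_cr_datasets(
        studies, grid, config.resize_factor, rc)
    split = evaluation.make_fold_split(
        [s.subject_id for s in studies],
        [int(s.label == "malignant") for s in studies],
        k=config.k_folds, seed=config.seed, ratio=config.split_ratio)
    return ExperimentContext(config, studies, manifest, grid, datasets,
                             stats, split)


def run_experiment_1(ctx: ExperimentContext,
                     crs: list | None = None) -> dict:
    """Train and test at each single CR; returns cr -> (EvalCell, models)."""
    crs = crs if crs is not None else ctx.cr_grid
    out = {}
    for cr in crs:
        models = evaluation.train_fold_models(
            ctx.datasets, cr, ctx.split, ctx.config.model, ctx.config.train)
        cell = evaluation.evaluate_models(models, ctx.datasets, cr, [cr],
                                          ctx.split)[0]
        logger.info("CR %s: AUROC %.3f +/- %.3f", cr, cell.auroc_mean,
                    cell.auroc_sd)
        out[cr] = {"cell": cell, "models": models}
    return out


def run_experiment_2(ctx: ExperimentContext, aug_prefixes=None,
                     matrix: bool = True) -> dict:
    """Cross-CR matrix plus nested mixed-CR augmentation models.

    ``aug_prefixes``: list of CR lists to mix into training sets; the
    default is the nested prefixes of the grid starting at CR 1.
    """
    result: dict = {}
    if matrix:
        result["matrix"] = evaluation.build_cr_matrix(
            ctx.datasets, ctx.cr_grid, ctx.config.model, ctx.config.train,
            ctx.split)
    if aug_prefixes is None:
        aug_prefixes = [ctx.cr_grid[:i + 1] for i in range(len(ctx.cr_grid))]
    aug_cells = {}
    for cr_list in aug_prefixes:
        cells = _augmentation_run(ctx, cr_list)
        aug_cells[tuple(cr_list)] = cells
    result["augmentation"] = aug_cells
    return result


def _augmentation_run(ctx: ExperimentContext, cr_list):
    """Five-fold models on the union of the training subjects' images at
    every CR in ``cr_list``, evaluated on each single-CR test set."""
    from . import cnn3

    base = ctx.datasets[cr_list[0]]
    h, w = next(iter(base.values())).left.pixels.shape
    models = []
    for j, fold in enumerate(ctx.split.folds):
        train_sides = evaluation.augment_with_crs(
            ctx.datasets, cr_list, fold["train"])
        val_sides = evaluation._sides_of(base, fold["val"])
        seed = ctx.config.train.seed * 100 + j
        model = cnn3.build_model(ctx.config.model, h, w, seed=seed)
        cfg = cnn3.TrainConfig(**{**ctx.config.train.__dict__, "seed": seed})
        cnn3.train(model, train_sides, val_sides, cfg)
        models.append(model)
    return evaluation.evaluate_models(models, ctx.datasets,
                                      float(cr_list[0]), ctx.cr_grid,
                                      ctx.split)


def run_robustness_suite(seed: int, n_subjects: int = 400,
                         separability: float = 0.8, epochs: int = 20,
                         saliency_quantile: float = 0.8) -> dict:
    """The desk-scale robustness analysis in one call.

    Grid: CR 1 (uncompressed), CR 15 (mild), and an extreme CR probed at
    ~0.9x the reachable maximum. Runs five-fold single-CR training at the
    low and extreme conditions, the mixed-CR augmentation arm, and
    Grad-CAM lesion-encapsulation scoring of correctly classified
    malignant test studies for both single-CR model families.

    Returns a flat dict of the headline numbers plus the underlying
    EvalCells (under "cells") for reporting.
    """
    from . import saliency as saliency_mod

    cfg = ExperimentConfig(n_subjects=n_subjects, seed=seed,
                           separability=separability)
    cfg.train = TrainConfig(epochs=epochs, seed=seed)
    studies, _ = synthdata.generate_cohort(
        cfg.seed, cfg.n_subjects, cfg.class_weights, cfg.width, cfg.height,
        cfg.separability)
    sample = studies[0].views["LCC"].pixels
    extreme = desk_extreme_crs(sample, fractions=(0.95,))[0]
    grid = [1, 15, extreme]
    rc = codec.RateControlConfig(tolerance=cfg.rate_tolerance)
    datasets, stats = evaluation.materialize_cr_datasets(
        studies, grid, cfg.resize_factor, rc)
    split = evaluation.make_fold_split(
        [s.subject_id for s in studies],
        [int(s.label == "malignant") for s in studies],
        k=cfg.k_folds, seed=cfg.seed, ratio=cfg.split_ratio)

    masks_by_subject = {s.subject_id: s for s in studies}

    def _median_encapsulation(models, test_cr):
        encs = []
        for model, fold in zip(models, split.folds):
            for sid in fold["test"]:
                pair = datasets[test_cr][sid]
                if pair.label != 1:
                    continue
                score = cnn3_predict(model, pair)
                lesion_side = (pair.left if pair.left.mask is not None
                               and pair.left.mask.any() else pair.right)
                if lesion_side.mask is None or not lesion_side.mask.any():
                    continue
                res = saliency_mod.grad_cam(model, lesion_side,
                                            quantile=saliency_quantile)
                encs.append((score > 0.5, res.encapsulation))
        correct = [e for ok, e in encs if ok]
        pool = correct if correct else [e for _, e in encs]
        return float(np.median(pool)) if pool else float("nan"), len(correct)

    def cnn3_predict(model, pair):
        from .cnn3 import predict_study

        return predict_study(model, pair.left, pair.right)

    # five-fold single-CR families at the low and extreme conditions
    low_models = evaluation.train_fold_models(datasets, 1, split,
                                              cfg.model, cfg.train)
    ext_models = evaluation.train_fold_models(datasets, extreme, split,
                                              cfg.model, cfg.train)
    low_cell = evaluation.evaluate_models(low_models, datasets, 1,
                                          [1, extreme], split)
    ext_cell = evaluation.evaluate_models(ext_models, datasets, extreme,
                                          [extreme], split)[0]

    # mixed-CR augmentation arm
    h, w = next(iter(datasets[1].values())).left.pixels.shape
    aug_models = []
    for j, fold in enumerate(split.folds):
        train_sides = evaluation.augment_with_crs(datasets, grid,
                                                  fold["train"])
        val_sides = evaluation._sides_of(datasets[1], fold["val"])
        fold_seed = cfg.train.seed * 100 + j
        model = cnn3_build(cfg.model, h, w, fold_seed)
        from .cnn3 import train as cnn3_train

        cnn3_train(model, train_sides, val_sides,
                   TrainConfig(**{**cfg.train.__dict__, "seed": fold_seed}))
        aug_models.append(model)
    aug_cell = evaluation.evaluate_models(aug_models, datasets, 1,
                                          [extreme], split)[0]

    enc_low, n_low = _median_encapsulation(low_models, 1)
    enc_ext, n_ext = _median_encapsulation(ext_models, extreme)

    ach = [r["achieved_cr"] for r in stats if r["target_cr"] == extreme]
    psnr15 = [r["psnr_db"] for r in stats if r["target_cr"] == 15]
    psnr_ext = [r["psnr_db"] for r in stats if r["target_cr"] == extreme]
    return {
        "extreme_cr": extreme,
        "achieved_extreme_cr_mean": float(np.mean(ach)),
        "psnr_cr15_mean": float(np.mean(psnr15)),
        "psnr_extreme_mean": float(np.mean(psnr_ext)),
        "auroc_low": low_cell[0].auroc_mean,
        "auroc_low_sd": low_cell[0].auroc_sd,
        "auprc_low": low_cell[0].auprc_mean,
        "auroc_extreme": ext_cell.auroc_mean,
        "auroc_extreme_sd": ext_cell.auroc_sd,
        "auprc_extreme": ext_cell.auprc_mean,
        "auroc_gap": low_cell[0].auroc_mean - ext_cell.auroc_mean,
        "auroc_low_model_on_extreme": low_cell[1].auroc_mean,
        "auroc_augmented_on_extreme": aug_cell.auroc_mean,
        "augmentation_gain": aug_cell.auroc_mean - low_cell[1].auroc_mean,
        "median_encapsulation_low": enc_low,
        "median_encapsulation_extreme": enc_ext,
        "n_correct_malignant_low": n_low,
        "n_correct_malignant_extreme": n_ext,
        "cells": {"low": low_cell[0], "low_on_extreme": low_cell[1],
                  "extreme": ext_cell, "augmented_on_extreme": aug_cell},
    }


def cnn3_build(model_cfg, h, w, seed):
    from .cnn3 import build_model

    return build_model(model_cfg, h, w, seed=seed)


# ---------------------------------------------------------------------------
# tidy output


def cells_to_frame(cells) -> pd.DataFrame:
    rows = []
    for cell in cells:
        rows.append({"train_cr": cell.train_cr, "test_cr": cell.test_cr,
                     "auroc_mean": cell.auroc_mean, "auroc_sd": cell.auroc_sd,
                     "auroc_ci_low": cell.auroc_ci[0],
                     "auroc_ci_high": cell.auroc_ci[1],
                     "auprc_mean": cell.auprc_mean, "auprc_sd": cell.auprc_sd,
                     "auprc_ci_low": cell.auprc_ci[0],
                     "auprc_ci_high": cell.auprc_ci[1]})
    return pd.DataFrame(rows)


def write_provenance(outdir, config: ExperimentConfig, cr_grid,
                     extra: dict | None = None):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {"config": _config_dict(config), "cr_grid": list(cr_grid)}
    if extra:
        payload.update(extra)
    (outdir / "provenance.json").write_text(json.dumps(payload, indent=2))


def _config_dict(config: ExperimentConfig) -> dict:
    d = asdict(config)
    return d
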