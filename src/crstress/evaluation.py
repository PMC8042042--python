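"""Cross-validated evaluation across compression ratios.

This module owns the experimental design: subject-level five-fold
cross-validation with a 7:1:2 train/validation/test split, ROC and PR
summary metrics with fold-level 95% confidence intervals, the
train-CR x test-CR generalization matrix, and the mixed-CR augmentation
of a training set.

AUROC is trapezoidal ROC integration (equivalently the concordance
probability with ties counted half); AUPRC is step-wise integration in
the average-precision style, whose baseline for uninformative scores is
the prevalence. Confidence intervals are the normal approximation over
fold metrics: mean +/- 1.96 * sd / sqrt(k).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import cnn3, codec
from .preprocess import SideInput, preprocess_study

logger = logging.getLogger(__name__)


def auroc(scores, labels) -> float:
    """Area under the ROC curve; needs both classes present."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined for single-class labels")
    return float(roc_auc_score(labels, scores))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve (step integration)."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("AUPRC undefined without positive labels")
    return float(average_precision_score(labels, scores))


def curve_points(scores, labels):
    """ROC and PR curve coordinates as a tidy frame (curve, x, y,
    threshold) for plotting or export."""
    import pandas as pd
    from sklearn.metrics import precision_recall_curve, roc_curve

    fpr, tpr, roc_th = roc_curve(labels, scores)
    prec, rec, pr_th = precision_recall_curve(labels, scores)
    roc = pd.DataFrame({"curve": "roc", "x": fpr, "y": tpr,
                        "threshold": roc_th})
    pr = pd.DataFrame({"curve": "pr", "x": rec, "y": prec,
                       "threshold": np.append(pr_th, np.nan)})
    return pd.concat([roc, pr], ignore_index=True)


# ---------------------------------------------------------------------------
# materialized per-CR datasets


@dataclass
class SidePair:
    """Both preprocessed sides of one study at one CR."""

    subject_id: str
    left: SideInput
    right: SideInput
    label: int


def materialize_cr_datasets(studies, crs, factor: float = 0.3,
                            rc_config: codec.RateControlConfig | None = None):
    """Compress every study at every CR and preprocess into side inputs.

    Returns ``(datasets, stats)`` where ``datasets[cr][subject_id]`` is a
    :class:`SidePair` and ``stats`` rows record achieved CR and PSNR per
    view. CR 1 uses the stored (uncompressed) pixels directly.
    """
    datasets: dict[float, dict[str, SidePair]] = {}
    stats = []
    for cr in crs:
        per_subject = {}
        for study in studies:
            override = None
            if cr != 1:
                override = {}
                for view, res in codec.compress_study_views(
                        study, cr, rc_config).items():
                    override[view] = codec.decode(res.codestream)
                    stats.append({"subject_id": study.subject_id, "view": view,
                                  "target_cr": cr,
                                  "achieved_cr": res.achieved_cr,
                                  "psnr_db": res.psnr_db})
            left, right = preprocess_study(study, factor, override, source_cr=cr)
            per_subject[study.subject_id] = SidePair(
                study.subject_id, left, right, left.label)
        datasets[cr] = per_subject
    return datasets, stats


# ---------------------------------------------------------------------------
# subject-level folds


@dataclass
class FoldSplit:
    """Per-fold train/validation/test subject-id lists."""

    k: int
    folds: list[dict]  # {"train": [...], "val": [...], "test": [...]}
    ratio: tuple[int, int, int] = (7, 1, 2)

    def __post_init__(self):
        for f in self.folds:
            roles = [set(f["train"]), set(f["val"]), set(f["test"])]
            if roles[0] & roles[1] or roles[0] & roles[2] or roles[1] & roles[2]:
                raise ValueError("a subject appears in two roles within a fold")


def make_fold_split(subject_ids, labels, k: int = 5, seed: int = 0,
                    ratio=(7, 1, 2)) -> FoldSplit:
    """Stratified subject-level folds: the k test sets partition the
    cohort; each fold's remainder is split train:val in ratio[0]:ratio[1]."""
    subject_ids = np.asarray(subject_ids)
    labels = np.asarray(labels)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for j, (rest_idx, test_idx) in enumerate(skf.split(subject_ids, labels)):
        val_frac = ratio[1] / (ratio[0] + ratio[1])
        train_ids, val_ids = train_test_split(
            subject_ids[rest_idx], test_size=val_frac,
            stratify=labels[rest_idx], random_state=seed * 1000 + j)
        folds.append({"train": list(train_ids), "val": list(val_ids),
                      "test": list(subject_ids[test_idx])})
    return FoldSplit(k, folds, tuple(ratio))


# ---------------------------------------------------------------------------
# aggregation


@dataclass
class EvalCell:
    """AUROC/AUPRC summary over folds for one (train CR, test CR) pair."""

    train_cr: float
    test_cr: float
    fold_aurocs: list[float]
    fold_auprcs: list[float]
    auroc_mean: float = field(init=False)
    auroc_sd: float = field(init=False)
    auroc_ci: tuple[float, float] = field(init=False)
    auprc_mean: float = field(init=False)
    auprc_sd: float = field(init=False)
    auprc_ci: tuple[float, float] = field(init=False)

    def __post_init__(self):
        for name in ("auroc", "auprc"):
            vals = np.asarray(getattr(self, f"fold_{name}s"), dtype=float)
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            half = 1.96 * sd / np.sqrt(len(vals))
            setattr(self, f"{name}_mean", mean)
            setattr(self, f"{name}_sd", sd)
            setattr(self, f"{name}_ci", (mean - half, mean + half))


@dataclass
class CRMatrix:
    cr_grid: list[float]
    cells: dict  # (train_cr, test_cr) -> EvalCell

    def cell(self, train_cr, test_cr) -> EvalCell:
        return self.cells[(train_cr, test_cr)]


def _sides_of(dataset, subject_ids) -> list[SideInput]:
    out = []
    for sid in subject_ids:
        pair = dataset[sid]
        out.extend([pair.left, pair.right])
    return out


def _study_scores(model, dataset, subject_ids):
    scores = [cnn3.predict_study(model, dataset[s].left, dataset[s].right)
              for s in subject_ids]
    labels = [dataset[s].label for s in subject_ids]
    return np.array(scores), np.array(labels)


def train_fold_models(datasets, train_cr, split: FoldSplit,
                      model_cfg: cnn3.ModelConfig | None = None,
                      train_cfg: cnn3.TrainConfig | None = None):
    """One trained model per fold, all on images at ``train_cr``."""
    model_cfg = model_cfg or cnn3.ModelConfig()
    train_cfg = train_cfg or cnn3.TrainConfig()
    dataset = datasets[train_cr]
    some_pair = next(iter(dataset.values()))
    h, w = some_pair.left.pixels.shape
    models = []
    for j, fold in enumerate(split.folds):
        model = cnn3.build_model(model_cfg, h, w, seed=train_cfg.seed * 100 + j)
        fold_cfg = cnn3.TrainConfig(**{**train_cfg.__dict__,
                                       "seed": train_cfg.seed * 100 + j})
        cnn3.train(model, _sides_of(dataset, fold["train"]),
                   _sides_of(dataset, fold["val"]), fold_cfg)
        models.append(model)
    return models


def evaluate_models(models, datasets, train_cr, test_crs,
                    split: FoldSplit) -> list[EvalCell]:
    """Score per-fold models on the fold test subjects at every test CR."""
    cells = []
    for test_cr in test_crs:
        aurocs, auprcs = [], []
        for model, fold in zip(models, split.folds):
            scores, labels = _study_scores(model, datasets[test_cr],
                                           fold["test"])
            if len(np.unique(labels)) < 2:
                warnings.warn(f"fold test set single-class at CR {test_cr}; "
                              "fold skipped")
                continue
            aurocs.append(auroc(scores, labels))
            auprcs.append(auprc(scores, labels))
        cells.append(EvalCell(train_cr, test_cr, aurocs, auprcs))
    return cells


def crossval(datasets, train_cr, test_crs, model_cfg=None, train_cfg=None,
             split: FoldSplit | None = None) -> list[EvalCell]:
    """Five-fold cross-validation: train at one CR, test at many."""
    if split is None:
        raise ValueError("a FoldSplit is required")
    models = train_fold_models(datasets, train_cr, split, model_cfg, train_cfg)
    return evaluate_models(models, datasets, train_cr, test_crs, split)


def build_cr_matrix(datasets, cr_grid, model_cfg=None, train_cfg=None,
                    split: FoldSplit | None = None) -> CRMatrix:
    """The full ordered-pair train-CR x test-CR generalization matrix."""
    cells = {}
    for train_cr in cr_grid:
        for cell in crossval(datasets, train_cr, list(cr_grid),
                             model_cfg, train_cfg, split):
            cells[(train_cr, cell.test_cr)] = cell
    return CRMatrix(list(cr_grid), cells)


def augment_with_crs(datasets, cr_list, subject_ids) -> list[SideInput]:
    """Training set augmented by compression: the union over ``cr_list`` of
    every training subject's side inputs. Test/validation sets are built
    separately and stay untouched."""
    if not cr_list:
        raise ValueError("cr_list must not be empty")
    out = []
    for cr in cr_list:
        out.extend(_sides_of(datasets[cr], subject_ids))
    return out
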