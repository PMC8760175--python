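"""Nested cross-validation protocol and evaluation metrics.

Outer stratified 10-fold cross-validation estimates generalization; inside
every outer training split an inner stratified 5-fold grid search selects
each voter's hyperparameters.  Reported metrics follow the confusion-matrix
conventions with AIE as the positive class:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)          recall = TPR = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)
    FPR       = FP / (TN + FP)

AUC is the area under the ROC curve (TPR vs FPR over thresholds), which
equals the Mann-Whitney statistic P(score+ > score-) + 0.5 P(equal).
Zero-denominator ratios are reported as undefined (None), never as 0.
Per-(family, mode) results and the ensemble row are aggregated as mean +/-
sample standard deviation over the outer folds, plus confusion counts
pooled over every outer test prediction.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from aievote.dataio import ACQ, AIE, Dataset
from aievote.ensemble import VotePanel, ensemble_predict, train_panel
from aievote.featurize import (
    FINGERPRINT_MODES,
    QUANTITATIVE_MODE,
    FeatureBlock,
    FeaturizeConfig,
    featurize_dataset,
)
from aievote.fuse import apply_fusion, fit_fusion, multimodal_mode_name
from aievote.models import FAMILIES, encode_labels, predict_labels, predict_scores
from aievote.util import stage_seed

ENSEMBLE_KEY = "ensemble"


@dataclasses.dataclass(frozen=True)
class FoldSplit:
    """A stratified partition of record indices into K folds."""

    assignments: np.ndarray
    K: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def make_folds(labels: Sequence[str], K: int = 10, seed: int = 0) -> FoldSplit:
    """Stratified K-fold assignment, deterministic under the seed."""
    y = encode_labels(labels)
    if len(y) < K:
        raise ValueError(f"need at least K={K} samples, got {len(y)}")
    counts = np.bincount(y, minlength=2)
    if counts.min() < K:
        raise ValueError(
            f"each class needs >= K={K} members for stratification, got {counts.tolist()}"
        )
    splitter = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    assignments = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
        assignments[test_idx] = fold
    return FoldSplit(assignments, K, seed)


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN with AIE as the positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_labels(cls, y_true: Sequence[str], y_pred: Sequence[str]) -> "ConfusionCounts":
        t = encode_labels(y_true)
        p = encode_labels(y_pred)
        return cls(
            TP=int(((t == 1) & (p == 1)).sum()),
            TN=int(((t == 0) & (p == 0)).sum()),
            FP=int(((t == 0) & (p == 1)).sum()),
            FN=int(((t == 1) & (p == 0)).sum()),
        )

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.TN + other.TN, self.FP + other.FP, self.FN + other.FN
        )


@dataclasses.dataclass
class MetricsReport:
    """Confusion-matrix-derived metrics; None marks an undefined ratio."""

    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None
    tpr: float | None
    fpr: float | None
    auc: float | None = None

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Exact metric formulas from pooled confusion counts (AUC excluded)."""
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    precision = _ratio(c.TP, c.TP + c.FP)
    recall = _ratio(c.TP, c.TP + c.FN)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(
        accuracy=(c.TP + c.TN) / c.total,
        precision=precision,
        recall=recall,
        f1=f1,
        tpr=recall,
        fpr=_ratio(c.FP, c.TN + c.FP),
    )


def compute_auc(scores: Sequence[float], labels: Sequence[str]) -> float:
    """Area under the ROC curve for positive class AIE."""
    y = encode_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=np.float64)))


@dataclasses.dataclass
class CVConfig:
    """Everything run_cv needs: protocol sizes, modality, seeds, switches."""

    multimodal: bool = False
    outer_folds: int = 10
    inner_folds: int = 5
    seed: int = 0
    families: tuple[str, ...] = FAMILIES
    fingerprint_modes: tuple[str, ...] = FINGERPRINT_MODES
    grid_preset: str = "full"
    fold_safe_fusion: bool = False
    tie_break: str = "majority-class"
    scoring: str = "accuracy"
    featurize: FeaturizeConfig = dataclasses.field(default_factory=FeaturizeConfig)

    @property
    def mode_names(self) -> list[str]:
        if self.multimodal:
            return [multimodal_mode_name(m) for m in self.fingerprint_modes]
        return [*self.fingerprint_modes, QUANTITATIVE_MODE]

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["featurize"]["descriptor_names"] = list(self.featurize.descriptor_names)
        return d


@dataclasses.dataclass
class CellResult:
    """Per-fold and aggregated results for one (family, mode) or the ensemble."""

    per_fold: list[dict]
    mean: dict
    std: dict
    pooled_confusion: ConfusionCounts

    def as_dict(self) -> dict:
        return {
            "per_fold": self.per_fold,
            "mean": self.mean,
            "std": self.std,
            "pooled_confusion": dataclasses.asdict(self.pooled_confusion),
        }


@dataclasses.dataclass
class CVReport:
    """Full nested-CV results for every voter cell plus the ensemble."""

    config: dict
    cells: dict[str, CellResult]
    ensemble: CellResult
    fold_sizes: list[int]
    manifest: dict

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "config": self.config,
            "fold_sizes": self.fold_sizes,
            "cells": {k: v.as_dict() for k, v in self.cells.items()},
            "ensemble": self.ensemble.as_dict(),
            "manifest": self.manifest,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_table(self, path: str | Path | None = None):
        """Render the mean +/- std table (rows: modes per family + ensemble)."""
        import pandas as pd

        def cell(mean: dict, std: dict, key: str) -> str:
            m, s = mean.get(key), std.get(key)
            if m is None:
                return "undefined"
            return f"{m:.4f} ± {s:.4f}"

        rows = []
        for name, res in self.cells.items():
            family, mode = name.split("|", 1)
            rows.append(
                {
                    "method": family,
                    "mode": mode,
                    "train_accuracy": cell(res.mean, res.std, "train_accuracy"),
                    "test_accuracy": cell(res.mean, res.std, "test_accuracy"),
                    "auc": cell(res.mean, res.std, "auc"),
                    "f1": cell(res.mean, res.std, "f1"),
                }
            )
        rows.append(
            {
                "method": ENSEMBLE_KEY,
                "mode": "-",
                "train_accuracy": "-",
                "test_accuracy": cell(self.ensemble.mean, self.ensemble.std, "test_accuracy"),
                "auc": cell(self.ensemble.mean, self.ensemble.std, "auc"),
                "f1": cell(self.ensemble.mean, self.ensemble.std, "f1"),
            }
        )
        frame = pd.DataFrame(rows)
        if path is not None:
            frame.to_csv(path, index=False)
        return frame


def _aggregate(per_fold: list[dict], keys: Sequence[str]) -> tuple[dict, dict]:
    """Mean and sample std over folds, skipping undefined (None) entries."""
    mean: dict = {}
    std: dict = {}
    for key in keys:
        values = [f[key] for f in per_fold if f.get(key) is not None]
        if not values:
            mean[key] = None
            std[key] = None
            continue
        mean[key] = float(np.mean(values))
        std[key] = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return mean, std


def _fold_metrics(y_true, y_pred, scores) -> dict:
    counts = ConfusionCounts.from_labels(y_true, y_pred)
    report = compute_metrics(counts)
    out = {
        "test_accuracy": report.accuracy,
        "f1": report.f1,
        "precision": report.precision,
        "recall": report.recall,
    }
    try:
        out["auc"] = compute_auc(scores, y_true)
    except ValueError:
        out["auc"] = None
    return out, counts


def _mode_matrices_for_fold(
    blocks: Mapping[str, FeatureBlock],
    config: CVConfig,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    global_matrices: Mapping[str, np.ndarray] | None,
) -> tuple[dict, dict]:
    """Training and test matrices per mode for one outer fold."""
    if not config.multimodal:
        mats = {m: blocks[m].matrix for m in config.mode_names}
        return (
            {m: mats[m][train_idx] for m in mats},
            {m: mats[m][test_idx] for m in mats},
        )
    if not config.fold_safe_fusion:
        assert global_matrices is not None
        return (
            {m: global_matrices[m][train_idx] for m in global_matrices},
            {m: global_matrices[m][test_idx] for m in global_matrices},
        )
    # leakage-safe: refit PCA + z-score statistics on the training split only
    train_mats: dict = {}
    test_mats: dict = {}
    quant = blocks[QUANTITATIVE_MODE]
    for fp_mode in config.fingerprint_modes:
        fp = blocks[fp_mode]
        fp_train = FeatureBlock(fp.mode, fp.matrix[train_idx], [fp.row_ids[i] for i in train_idx])
        qt_train = FeatureBlock(
            quant.mode, quant.matrix[train_idx], [quant.row_ids[i] for i in train_idx],
            quant.feature_names,
        )
        model = fit_fusion(fp_train, qt_train)
        name = multimodal_mode_name(fp_mode)
        train_mats[name] = apply_fusion(model, fp_train, qt_train).matrix
        fp_test = FeatureBlock(fp.mode, fp.matrix[test_idx], [fp.row_ids[i] for i in test_idx])
        qt_test = FeatureBlock(
            quant.mode, quant.matrix[test_idx], [quant.row_ids[i] for i in test_idx],
            quant.feature_names,
        )
        test_mats[name] = apply_fusion(model, fp_test, qt_test).matrix
    return train_mats, test_mats


def run_cv(
    dataset: Dataset,
    config: CVConfig | None = None,
    blocks: Mapping[str, FeatureBlock] | None = None,
    cache_dir: str | Path | None = None,
) -> CVReport:
    """Run the full nested cross-validation protocol on a labeled dataset.

    For every (family, mode) voter cell and for the majority-vote ensemble,
    reports per-fold train accuracy and test accuracy/AUC/F1, their mean
    +/- sample std over the outer folds, and pooled confusion counts.
    A manifest of seeds, versions and design switches is attached.
    """
    config = config or CVConfig()
    labels = dataset.labels
    if any(l is None for l in labels):
        raise ValueError("run_cv requires a fully labeled dataset")
    counts = dataset.class_counts
    if min(counts.values()) == 0:
        raise ValueError(f"both classes required, got counts {counts}")
    majority_class = max(counts, key=lambda c: (counts[c], c == ACQ))

    if blocks is None:
        needed = (*config.fingerprint_modes, QUANTITATIVE_MODE)
        blocks = {
            m: featurize_dataset(dataset, m, config.featurize, cache_dir) for m in needed
        }

    global_matrices = None
    if config.multimodal and not config.fold_safe_fusion:
        # default scope: fusion fitted once on the full dataset before CV
        quant = blocks[QUANTITATIVE_MODE]
        global_matrices = {}
        for fp_mode in config.fingerprint_modes:
            model = fit_fusion(blocks[fp_mode], quant)
            global_matrices[multimodal_mode_name(fp_mode)] = apply_fusion(
                model, blocks[fp_mode], quant
            ).matrix

    folds = make_folds(labels, config.outer_folds, stage_seed(config.seed, "folds"))
    y = np.asarray(labels)
    mode_names = config.mode_names
    cell_folds: dict[str, list[dict]] = {
        f"{fam}|{mode}": [] for fam in config.families for mode in mode_names
    }
    cell_conf: dict[str, ConfusionCounts] = {
        k: ConfusionCounts(0, 0, 0, 0) for k in cell_folds
    }
    ens_folds: list[dict] = []
    ens_conf = ConfusionCounts(0, 0, 0, 0)
    fold_sizes: list[int] = []

    for fold in range(folds.K):
        train_idx = folds.train_indices(fold)
        test_idx = folds.test_indices(fold)
        fold_sizes.append(len(test_idx))
        train_mats, test_mats = _mode_matrices_for_fold(
            blocks, config, train_idx, test_idx, global_matrices
        )
        tune_seed = stage_seed(config.seed, f"tune-fold{fold}")
        try:
            panel = train_panel(
                config.families,
                train_mats,
                y[train_idx],
                modality="multi" if config.multimodal else "single",
                inner_folds=config.inner_folds,
                seed=tune_seed,
                grid_preset=config.grid_preset,
                scoring=config.scoring,
            )
        except Exception as exc:
            raise RuntimeError(f"tuning failed at fold {fold}: {exc}") from exc
        for voter in panel.voters:
            key = f"{voter.family}|{voter.mode}"
            try:
                train_pred = predict_labels(voter, train_mats[voter.mode])
                test_pred = predict_labels(voter, test_mats[voter.mode])
                scores = predict_scores(voter, test_mats[voter.mode])
            except Exception as exc:
                raise RuntimeError(
                    f"prediction failed at (family={voter.family}, mode={voter.mode}, "
                    f"fold={fold}): {exc}"
                ) from exc
            metrics, conf = _fold_metrics(y[test_idx], test_pred, scores)
            metrics["fold"] = fold
            metrics["train_accuracy"] = float(
                np.mean(train_pred == y[train_idx])
            )
            metrics["chosen_params"] = voter.chosen_params
            cell_folds[key].append(metrics)
            cell_conf[key] = cell_conf[key] + conf
        votes = ensemble_predict(
            panel,
            test_mats,
            ids=[dataset.ids[i] for i in test_idx],
            tie_break=config.tie_break,
            majority_class=majority_class,
        )
        ens_pred = np.array([v.final for v in votes])
        ens_scores = np.array([v.vote_fraction for v in votes])
        metrics, conf = _fold_metrics(y[test_idx], ens_pred, ens_scores)
        metrics["fold"] = fold
        metrics["n_tied"] = int(sum(v.tied for v in votes))
        ens_folds.append(metrics)
        ens_conf = ens_conf + conf

    agg_keys = ("train_accuracy", "test_accuracy", "auc", "f1", "precision", "recall")
    cells = {}
    for key, per_fold in cell_folds.items():
        mean, std = _aggregate(per_fold, agg_keys)
        cells[key] = CellResult(per_fold, mean, std, cell_conf[key])
    ens_mean, ens_std = _aggregate(ens_folds, agg_keys[1:])
    ensemble = CellResult(ens_folds, ens_mean, ens_std, ens_conf)

    import rdkit
    import sklearn

    manifest = {
        "seed": config.seed,
        "fold_seed": stage_seed(config.seed, "folds"),
        "majority_class": majority_class,
        "n_voters": len(config.families) * len(mode_names),
        "versions": {
            "numpy": np.__version__,
            "sklearn": sklearn.__version__,
            "rdkit": rdkit.__version__,
        },
        "decisions": {
            "fusion_fit_scope": "per-fold" if config.fold_safe_fusion else "global",
            "tie_break": config.tie_break,
            "grid_preset": config.grid_preset,
            "inner_scoring": config.scoring,
            "stratified_outer_folds": True,
        },
    }
    return CVReport(config.as_dict(), cells, ensemble, fold_sizes, manifest)
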