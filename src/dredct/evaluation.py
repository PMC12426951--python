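"""Cross-validation harness, metrics, significance testing and ablation.

The evaluation protocol is stratified 5-fold cross-validation; within each
fold 10% of the training portion is held out for validation.  Metrics are
the 3 x 3 confusion matrix, accuracy and macro-averaged precision, recall
and F1.  Runs are compared with a Welch (unequal-variance) two-sample
t-test on per-fold accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import accuracy_score, confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .augment import AugmentationPolicy
from .enhancer import EnhancementConfig, enhance_image
from .io import CLASS_NAMES, DatasetManifest, load_manifest_images
from .model import TinyPatchClassifier, TrainConfig, _make_augment_fn, build_model

__all__ = [
    "FoldSplit",
    "MetricsReport",
    "TTestResult",
    "CVResult",
    "make_folds",
    "compute_metrics",
    "compare_runs",
    "run_cross_validation",
    "ablate_block_size",
]


@dataclass(frozen=True)
class FoldSplit:
    """One fold of the cross-validation partition (1-based fold index)."""

    fold: int
    train_idx: tuple[int, ...]
    val_idx: tuple[int, ...]
    test_idx: tuple[int, ...]

    def manifests(self, manifest: DatasetManifest):
        return (
            manifest.subset(self.train_idx),
            manifest.subset(self.val_idx),
            manifest.subset(self.test_idx),
        )


@dataclass(frozen=True)
class MetricsReport:
    """Per-run classification metrics over the fixed 3-class label set."""

    confusion: np.ndarray  # rows = true class, columns = predicted
    accuracy: float
    precision: float  # macro
    recall: float  # macro
    f1: float  # macro
    n: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "n": self.n,
        }


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    dof: float
    pvalue: float
    degenerate: bool = False


def _labels_of(obj) -> np.ndarray:
    if isinstance(obj, DatasetManifest):
        return np.asarray(obj.labels)
    return np.asarray(obj)


def make_folds(
    data, k: int = 5, val_fraction: float = 0.1, seed: int = 0
) -> list[FoldSplit]:
    """Stratified k-fold partition with an inner validation split.

    ``data`` is a :class:`DatasetManifest` or a label vector.  Test sets
    partition the dataset; within each fold's training portion,
    ``val_fraction`` is held out (stratified) for validation.
    """
    y = _labels_of(data)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small!r} has {counts.min()} samples; need >= k = {k} per class"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for fold, (train_all, test) in enumerate(skf.split(np.zeros(len(y)), y), start=1):
        # hold out val_fraction of the training portion, at least 1 per class
        n_val = max(int(np.ceil(val_fraction * len(train_all))), len(classes))
        sss = StratifiedShuffleSplit(
            n_splits=1, test_size=n_val, random_state=seed + fold
        )
        (tr_rel, va_rel), = sss.split(np.zeros(len(train_all)), y[train_all])
        folds.append(
            FoldSplit(
                fold=fold,
                train_idx=tuple(int(i) for i in train_all[tr_rel]),
                val_idx=tuple(int(i) for i in train_all[va_rel]),
                test_idx=tuple(int(i) for i in test),
            )
        )
    return folds


def compute_metrics(y_true, y_pred) -> MetricsReport:
    """Confusion matrix, accuracy and macro precision/recall/F1."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    bad = (set(y_true) | set(y_pred)) - set(CLASS_NAMES)
    if bad:
        raise ValueError(f"labels outside the class set: {sorted(bad)}")
    cm = confusion_matrix(y_true, y_pred, labels=list(CLASS_NAMES))
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=list(CLASS_NAMES), average="macro", zero_division=0
    )
    return MetricsReport(
        confusion=cm,
        accuracy=float(accuracy_score(y_true, y_pred)),
        precision=float(prec),
        recall=float(rec),
        f1=float(f1),
        n=len(y_true),
    )


def compare_runs(accuracies_a, accuracies_b) -> TTestResult:
    """Welch two-sample t-test on two groups of per-fold accuracies.

    Two groups that are both constant (zero variance) are degenerate: the
    statistic is undefined and the result is flagged with no p-value.
    """
    a = np.asarray(accuracies_a, dtype=np.float64)
    b = np.asarray(accuracies_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if a.std() == 0.0 and b.std() == 0.0:
        return TTestResult(np.nan, np.nan, np.nan, degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(
        statistic=float(res.statistic), dof=float(res.df), pvalue=float(res.pvalue)
    )


@dataclass(frozen=True)
class CVResult:
    """All per-fold reports of one cross-validated run."""

    reports: tuple[MetricsReport, ...]
    folds: tuple[FoldSplit, ...]

    @property
    def fold_accuracies(self) -> list[float]:
        return [r.accuracy for r in self.reports]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    def summary_frame(self) -> pd.DataFrame:
        rows = [dict(fold=f.fold, **r.to_dict()) for f, r in zip(self.folds, self.reports)]
        return pd.DataFrame(rows)


def _resolve_arrays(data, image_side: int):
    if isinstance(data, DatasetManifest):
        return load_manifest_images(data, side=image_side)
    X, y = data
    return np.asarray(X), np.asarray(y)


def run_cross_validation(
    data,
    k: int = 5,
    val_fraction: float = 0.1,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    enhancement: EnhancementConfig | None = None,
    augmentation: AugmentationPolicy | None = None,
    backbone: str = "tiny-test",
    model_params: dict | None = None,
) -> CVResult:
    """Train and evaluate one configuration across all k folds.

    ``data`` is a :class:`DatasetManifest` or an ``(X, y)`` pair of images
    and labels.  When ``enhancement`` is given every image (train, val and
    test alike) is enhanced once, before normalisation; augmentation, when
    given, is applied per epoch to training images only.
    """
    cfg = train_config or TrainConfig.for_tiny(seed=seed)
    X, y = _resolve_arrays(data, cfg.image_side)
    if enhancement is not None:
        X = np.stack([enhance_image(x, enhancement) for x in X]).astype(np.float32)
    folds = make_folds(y, k=k, val_fraction=val_fraction, seed=seed)
    reports = []
    for fs in folds:
        params = dict(
            learning_rate=cfg.learning_rate,
            batch_size=cfg.batch_size,
            epochs=cfg.epochs,
            seed=cfg.seed + fs.fold,
        )
        params.update(model_params or {})
        model = build_model(n_classes=len(CLASS_NAMES), backbone=backbone, **params)
        augment_fn = (
            _make_augment_fn(augmentation, cfg.seed + fs.fold)
            if augmentation is not None
            else None
        )
        tr, va, te = list(fs.train_idx), list(fs.val_idx), list(fs.test_idx)
        model.fit(X[tr], y[tr], X_val=X[va], y_val=y[va], augment_fn=augment_fn)
        reports.append(compute_metrics(y[te], model.predict(X[te])))
    return CVResult(reports=tuple(reports), folds=tuple(folds))


def ablate_block_size(
    data,
    sizes,
    train_config: TrainConfig | None = None,
    seed: int = 0,
    k: int = 5,
    val_fraction: float = 0.1,
    backbone: str = "tiny-test",
    model_params: dict | None = None,
) -> pd.DataFrame:
    """Accuracy versus enhancement block size on one fixed fold (fold 1).

    Duplicate sizes collapse to a single evaluation.  Returns a table with
    columns ``block_size`` and ``accuracy``.
    """
    sizes = list(sizes)
    if not sizes:
        raise ValueError("sizes must be non-empty")
    cfg = train_config or TrainConfig.for_tiny(seed=seed)
    X, y = _resolve_arrays(data, cfg.image_side)
    fs = make_folds(y, k=k, val_fraction=val_fraction, seed=seed)[0]
    tr, va, te = list(fs.train_idx), list(fs.val_idx), list(fs.test_idx)
    cache: dict[int, float] = {}
    rows = []
    for size in sizes:
        size = int(size)
        if size not in cache:
            enh = EnhancementConfig(block_size=size)
            X_enh = np.stack([enhance_image(x, enh) for x in X]).astype(np.float32)
            params = dict(
                learning_rate=cfg.learning_rate,
                batch_size=cfg.batch_size,
                epochs=cfg.epochs,
                seed=cfg.seed + fs.fold,
            )
            params.update(model_params or {})
            model = build_model(n_classes=len(CLASS_NAMES), backbone=backbone, **params)
            model.fit(X_enh[tr], y[tr], X_val=X_enh[va], y_val=y[va])
            cache[size] = compute_metrics(y[te], model.predict(X_enh[te])).accuracy
        rows.append({"block_size": size, "accuracy": cache[size]})
    return pd.DataFrame(rows).drop_duplicates().reset_index(drop=True)
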