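"""Data segmentation, Monte Carlo resampling, and model-performance metrics.

Classification metrics follow the one-vs-rest contingency definitions:
per-class TP/TN/FP/FN, precision TP/(TP+FP), recall TP/(TP+FN),
F1 = 2TP/(2TP+FP+FN), macro-averaged over classes.  Accuracy is the overall
fraction of correct predictions (trace of the confusion matrix over its
total), which coincides with (TP+TN)/n in the binary case.

Regression metrics: R^2 = 1 - SS_res/SS_tot and RMSE; on adulteration
fractions RMSE is conventionally reported in percent (RMSECV on the
training/cross-validation side, RMSEP on the prediction set).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .grid import SpectraSet

__all__ = [
    "split_origin_mc",
    "split_adulteration",
    "ConfusionMatrix",
    "confusion",
    "classification_metrics",
    "r_squared",
    "rmse",
    "EvaluationReport",
    "evaluate_origin_models",
]


# ---------------------------------------------------------------------------
# Splits

def split_origin_mc(spectra: SpectraSet, test_fraction: float = 1.0 / 3.0,
                    n_repeats: int = 20, seed: int = 0,
                    stratify_batches: bool = False
                    ) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Monte Carlo train/test partitions, stratified per class.

    Each repeat draws ``floor(test_fraction * n_class)`` test spectra per
    class without replacement (60 of 180 at the study design), independently
    across repeats.  ``stratify_batches=True`` instead holds out whole
    batches per class (a leakage-safe variant; the literal protocol samples
    spectra, so replicates of one batch may appear on both sides).
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    if spectra.label_kind != "origin":
        raise ValueError("origin-labelled spectra required")
    rng = np.random.default_rng(seed)
    classes = np.unique(spectra.labels)
    pairs = []
    for _ in range(n_repeats):
        test_idx: List[np.ndarray] = []
        for c in classes:
            idx = np.nonzero(spectra.labels == c)[0]
            if stratify_batches and spectra.batch_ids is not None:
                batches = np.unique(spectra.batch_ids[idx])
                n_hold = max(1, int(round(test_fraction * batches.size)))
                held = rng.choice(batches, size=n_hold, replace=False)
                test_idx.append(idx[np.isin(spectra.batch_ids[idx], held)])
            else:
                n_test = int(np.floor(test_fraction * idx.size))
                test_idx.append(rng.choice(idx, size=n_test, replace=False))
        test = np.sort(np.concatenate(test_idx))
        mask = np.ones(spectra.n, dtype=bool)
        mask[test] = False
        pairs.append((np.nonzero(mask)[0], test))
    return pairs


def split_adulteration(spectra: SpectraSet, seed: int = 0,
                       n_train_per_level: int = 13
                       ) -> Tuple[np.ndarray, np.ndarray]:
    """Per-level split of the mixture set: 13 train / 7 test of 20 replicates."""
    if spectra.label_kind != "fraction":
        raise ValueError("fraction-labelled spectra required")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for level in np.unique(spectra.labels):
        idx = np.nonzero(spectra.labels == level)[0]
        if idx.size != 20:
            raise ValueError(
                f"level {level} has {idx.size} replicates, expected 20")
        chosen = rng.choice(idx, size=n_train_per_level, replace=False)
        train_idx.append(np.sort(chosen))
        test_idx.append(np.setdiff1d(idx, chosen))
    return np.concatenate(train_idx), np.concatenate(test_idx)


# ---------------------------------------------------------------------------
# Metrics

@dataclass
class ConfusionMatrix:
    """c x c counts; rows are actual classes, columns predicted classes."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        c = self.counts.shape[0]
        if self.counts.shape != (c, c) or np.any(self.counts < 0):
            raise ValueError("confusion matrix must be square and non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    def one_vs_rest(self, k: int) -> Tuple[int, int, int, int]:
        """(TP, TN, FP, FN) treating class k as positive."""
        tp = int(self.counts[k, k])
        fn = int(self.counts[k].sum() - tp)
        fp = int(self.counts[:, k].sum() - tp)
        tn = self.n - tp - fn - fp
        return tp, tn, fp, fn


def confusion(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside 0..{n_classes - 1}")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def _safe_div(a: float, b: float) -> float:
    return a / b if b else 0.0


def classification_metrics(cm: ConfusionMatrix) -> Dict[str, float]:
    """Accuracy (overall) plus macro one-vs-rest precision/recall/F1."""
    n = cm.n
    if n == 0:
        raise ValueError("empty confusion matrix")
    acc = float(np.trace(cm.counts)) / n
    prec, rec, f1 = [], [], []
    for k in range(cm.n_classes):
        tp, tn, fp, fn = cm.one_vs_rest(k)
        prec.append(_safe_div(tp, tp + fp))
        rec.append(_safe_div(tp, tp + fn))
        f1.append(_safe_div(2 * tp, 2 * tp + fp + fn))
    return {
        "accuracy": acc,
        "precision": float(np.mean(prec)),
        "recall": float(np.mean(rec)),
        "f1": float(np.mean(f1)),
    }


def r_squared(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need >= 2 paired observations")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: zero variance in y_true")
    return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot


def rmse(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


# ---------------------------------------------------------------------------
# Monte Carlo model comparison

_METRICS = ("accuracy", "precision", "recall", "f1")


@dataclass
class EvaluationReport:
    """Per-repeat metric table plus mean +- std aggregation."""

    records: pd.DataFrame
    failures: List[str] = field(default_factory=list)

    def aggregate(self) -> pd.DataFrame:
        """Mean and std per (preprocessing, model, split, metric)."""
        long = self.records.melt(
            id_vars=["repeat", "preprocessing", "model", "split"],
            value_vars=list(_METRICS), var_name="metric")
        out = (long.groupby(["preprocessing", "model", "split", "metric"],
                            sort=False)["value"]
               .agg(["mean", "std"]).reset_index())
        out["std"] = out["std"].fillna(0.0)
        return out

    def to_csv(self, path) -> None:
        self.aggregate().to_csv(path, index=False)


def evaluate_origin_models(spectra: SpectraSet,
                           models: Dict[str, Callable[[int], object]],
                           preprocessors: Dict[str, Callable],
                           n_repeats: int = 20, seed: int = 0,
                           splits: Optional[Sequence[Tuple[np.ndarray,
                                                           np.ndarray]]] = None
                           ) -> EvaluationReport:
    """Full factorial (preprocessing x model) Monte Carlo evaluation.

    ``models`` maps a name to a factory ``f(seed) -> estimator`` exposing
    ``fit(X, y)`` / ``predict(X)``.  Preprocessors are row-wise transforms
    applied to the whole matrix before splitting (all are per-spectrum, so
    no information crosses the split).  Single-repeat failures are recorded
    in the report rather than raised.
    """
    if not models or not preprocessors:
        raise ValueError("model and preprocessing registries must be non-empty")
    if splits is None:
        splits = split_origin_mc(spectra, n_repeats=n_repeats, seed=seed)
    n_classes = int(spectra.labels.max()) + 1
    rows, failures = [], []
    for prep_name, prep in preprocessors.items():
        Xp = prep(spectra.X)
        for model_name, factory in models.items():
            for r, (tr, te) in enumerate(splits):
                try:
                    est = factory(seed + r)
                    est.fit(Xp[tr], spectra.labels[tr])
                    for split_name, idx in (("training", tr), ("test", te)):
                        pred = est.predict(Xp[idx])
                        cm = confusion(spectra.labels[idx], pred, n_classes)
                        row = {"repeat": r, "preprocessing": prep_name,
                               "model": model_name, "split": split_name}
                        row.update(classification_metrics(cm))
                        rows.append(row)
                except Exception as exc:  # recorded, not fatal
                    failures.append(
                        f"{prep_name}/{model_name}/repeat {r}: {exc}")
    return EvaluationReport(pd.DataFrame(rows), failures)
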