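"""Metrics, cross-validation and hyperparameter sweeps.

Sensitivity and specificity are defined with respect to an explicit positive
class (default ``"abnormal"``, the clinical detection target). The G-mean,
``sqrt(sensitivity × specificity)``, summarises performance independently of
the class distribution and is the criterion used to pick the class-weight
ratio: unlike the raw correct rate it cannot be inflated by sacrificing the
minority class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import forest as rf

POSITIVE_CLASS = "abnormal"


@dataclass
class ConfusionCounts:
    """2×2 confusion counts with the positive class recorded explicitly."""

    tp: int
    fn: int
    tn: int
    fp: int
    positive: str = POSITIVE_CLASS

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def confusion(
    y_true: Sequence[str], y_pred: Sequence[str], positive: str = POSITIVE_CLASS
) -> ConfusionCounts:
    yt = np.asarray(y_true, dtype=object)
    yp = np.asarray(y_pred, dtype=object)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have the same length")
    pos_t = yt == positive
    pos_p = yp == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        positive=positive,
    )


@dataclass
class Metrics:
    """Summary rates in [0, 1]; undefined ratios are NaN with a flag."""

    correct_rate: float
    sensitivity: float
    specificity: float
    f1: float
    g_mean: float
    f1_defined: bool = True
    counts: Optional[ConfusionCounts] = None

    def as_percent(self) -> dict:
        return {
            k: round(100.0 * v, 2)
            for k, v in {
                "correct_rate": self.correct_rate,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "f1": self.f1,
                "g_mean": self.g_mean,
            }.items()
        }


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Correct rate, sensitivity, specificity, F1 and G-mean from counts."""
    if counts.total <= 0:
        raise ValueError("no samples evaluated")
    sens = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else math.nan
    spec = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else math.nan
    correct = (counts.tp + counts.tn) / counts.total
    f1_defined = (counts.tp + counts.fp) > 0 and (counts.tp + counts.fn) > 0
    if f1_defined:
        prec = counts.tp / (counts.tp + counts.fp)
        rec = counts.tp / (counts.tp + counts.fn)
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
    else:
        f1 = math.nan
    g = math.sqrt(sens * spec) if not (math.isnan(sens) or math.isnan(spec)) else math.nan
    return Metrics(
        correct_rate=correct,
        sensitivity=sens,
        specificity=spec,
        f1=f1,
        g_mean=g,
        f1_defined=f1_defined,
        counts=counts,
    )


def oob_metrics(
    forest_: rf.Forest,
    X: np.ndarray,
    labels: Sequence[str],
    positive: str = POSITIVE_CLASS,
) -> Metrics:
    """Metrics from OOB-aggregated predictions over the training set."""
    pred, has = rf.oob_predictions(forest_, X)
    y = np.asarray(labels, dtype=object)
    return compute_metrics(confusion(y[has], pred[has], positive))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def stratified_folds(labels: Sequence[str], k: int, seed: int) -> List[np.ndarray]:
    """Disjoint stratified folds covering all samples (proportions ±1)."""
    y = np.asarray(labels, dtype=object)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = {c: int(np.sum(y == c)) for c in sorted(set(map(str, y)))}
    if min(counts.values()) < k and k > len(y):
        raise ValueError("k exceeds the number of samples")
    rng = np.random.default_rng(seed)
    folds: List[List[int]] = [[] for _ in range(k)]
    # deal class by class, carrying the fold pointer across classes so overall
    # fold sizes stay within one of each other
    pointer = 0
    for c in sorted(set(map(str, y))):
        idx = rng.permutation(np.nonzero(y == c)[0])
        for i in idx:
            folds[pointer % k].append(int(i))
            pointer += 1
    if any(len(f) == 0 for f in folds):
        raise ValueError(f"k={k} leaves an empty fold for n={len(y)}")
    return [np.sort(np.asarray(f)) for f in folds]


ClassifierFactory = Callable[[int], object]


def forest_factory(config: rf.ForestConfig) -> ClassifierFactory:
    """Default classifier factory: a weighted forest with a per-fold seed."""

    class _Clf:
        def __init__(self, seed: int):
            self.cfg = replace(config, seed=seed)
            self.model: Optional[rf.Forest] = None

        def fit(self, X, y):
            self.model = rf.fit(X, y, self.cfg)
            return self

        def predict(self, X):
            return rf.predict(self.model, X)[0]

    return _Clf


def kfold_cv(
    X: np.ndarray,
    labels: Sequence[str],
    k: int = 10,
    factory: Optional[ClassifierFactory] = None,
    seed: int = 0,
    positive: str = POSITIVE_CLASS,
) -> Tuple[List[Metrics], Metrics]:
    """Stratified k-fold CV: per-fold metrics plus pooled-count metrics."""
    factory = factory or forest_factory(rf.ForestConfig(n_tree=100))
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=object)
    folds = stratified_folds(labels, k, seed)
    per_fold = []
    pooled = ConfusionCounts(0, 0, 0, 0, positive)
    for j, test_idx in enumerate(folds):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        clf = factory(seed + j)
        clf.fit(X[train_mask], y[train_mask])
        pred = clf.predict(X[test_idx])
        c = confusion(y[test_idx], pred, positive)
        per_fold.append(compute_metrics(c))
        pooled = ConfusionCounts(
            pooled.tp + c.tp, pooled.fn + c.fn, pooled.tn + c.tn, pooled.fp + c.fp, positive
        )
    return per_fold, compute_metrics(pooled)


# ---------------------------------------------------------------------------
# Tuning sweeps
# ---------------------------------------------------------------------------

def _repeat_seeds(seed: int, repeats: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=repeats)


def sweep_ntree(
    X: np.ndarray,
    labels: Sequence[str],
    grid: Sequence[int],
    config: Optional[rf.ForestConfig] = None,
    repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean OOB error as the forest grows; the error should stabilise."""
    if not len(grid):
        raise ValueError("grid is empty")
    config = config or rf.ForestConfig()
    seeds = _repeat_seeds(seed, repeats)
    rows = []
    for n_tree in sorted(grid):
        errs = [
            rf.oob_error(rf.fit(X, labels, replace(config, n_tree=n_tree, seed=int(s))), X, labels)
            for s in seeds
        ]
        rows.append({"n_tree": n_tree, "oob_error": float(np.mean(errs))})
    return pd.DataFrame(rows)


def sweep_mtry(
    X: np.ndarray,
    labels: Sequence[str],
    grid: Sequence[int],
    n_tree: int = 1000,
    config: Optional[rf.ForestConfig] = None,
    repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean OOB error over candidate m_try values at a fixed forest size."""
    config = config or rf.ForestConfig()
    p = np.asarray(X).shape[1]
    if any(m < 1 or m > p for m in grid):
        raise ValueError(f"m_try grid values must lie in [1, {p}]")
    seeds = _repeat_seeds(seed, repeats)
    rows = []
    for m in sorted(grid):
        errs = [
            rf.oob_error(
                rf.fit(X, labels, replace(config, m_try=int(m), n_tree=n_tree, seed=int(s))),
                X,
                labels,
            )
            for s in seeds
        ]
        rows.append({"m_try": int(m), "oob_error": float(np.mean(errs))})
    return pd.DataFrame(rows)


def sweep_class_weight(
    X: np.ndarray,
    labels: Sequence[str],
    ratios: Sequence[float],
    config: Optional[rf.ForestConfig] = None,
    repeats: int = 5,
    seed: int = 0,
    positive: str = POSITIVE_CLASS,
) -> Tuple[pd.DataFrame, float]:
    """OOB metrics per abnormal:normal weight ratio; recommend argmax G-mean.

    Ties in G-mean go to the smaller ratio (least intervention).
    """
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be > 0")
    config = config or rf.ForestConfig()
    seeds = _repeat_seeds(seed, repeats)
    rows = []
    for ratio in ratios:
        cw = {"abnormal": float(ratio), "normal": 1.0}
        ms = []
        for s in seeds:
            f = rf.fit(X, labels, replace(config, class_weights=cw, seed=int(s)))
            ms.append(oob_metrics(f, X, labels, positive))
        rows.append(
            {
                "ratio": float(ratio),
                "correct_rate": float(np.mean([m.correct_rate for m in ms])),
                "g_mean": float(np.mean([m.g_mean for m in ms])),
                "sensitivity": float(np.mean([m.sensitivity for m in ms])),
                "specificity": float(np.mean([m.specificity for m in ms])),
            }
        )
    table = pd.DataFrame(rows)
    best = table.loc[table.g_mean.idxmax()]
    # idxmax takes the first maximum; rows follow the input ratio order, so
    # re-check for exact ties preferring the smallest ratio
    tied = table[np.isclose(table.g_mean, best.g_mean)]
    recommended = float(tied.ratio.min())
    return table, recommended
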