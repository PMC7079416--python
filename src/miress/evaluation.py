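"""Metrics and the repeated stratified 5-fold cross-validation protocol.

AUC is computed rank-wise (Mann-Whitney with midranks for ties), which
equals the trapezoidal area under the ROC curve.  Cross-validation
stratifies by class, repeats the whole k-fold split ``repeats`` times with
a fresh partition per repeat (seed + repeat index), pools the held-out
scores of each repeat into one ROC, and averages the per-repeat metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .gbm import BoostParams, fit, predict

__all__ = [
    "MetricError",
    "CVReport",
    "roc_auc",
    "roc_points",
    "confusion_metrics",
    "stratified_kfold",
    "cross_validate",
    "scan",
]

METRICS = ("auc", "acc", "precision", "recall", "f_measure")


class MetricError(ValueError):
    """Invalid input to a metric or protocol routine."""


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    classes = set(np.unique(labels))
    if not classes <= {0, 1}:
        raise MetricError(f"labels must be 0/1, got {sorted(classes)}")
    if classes != {0, 1}:
        raise MetricError("both classes must be present")
    return labels.astype(int)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve by the rank statistic.

    Equivalent to the probability that a random positive outscores a
    random negative, with ties counted half.
    """
    labels = _check_binary(np.asarray(labels))
    scores = np.asarray(scores, dtype=float)
    if scores.shape != labels.shape:
        raise MetricError("scores and labels differ in length")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = rankdata(scores)  # midranks for ties
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_points(scores: Sequence[float], labels: Sequence[int]) -> pd.DataFrame:
    """(FPR, TPR) points of the ROC curve, one row per distinct threshold."""
    labels = _check_binary(np.asarray(labels))
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    tp = np.concatenate([[0], np.cumsum(y)])
    fp = np.concatenate([[0], np.cumsum(1 - y)])
    # keep the last point of each tied-score run
    distinct = np.concatenate([np.diff(scores[order]) != 0, [True]])
    keep = np.concatenate([[True], distinct])
    return pd.DataFrame(
        {"fpr": fp[keep] / fp[-1], "tpr": tp[keep] / tp[-1]}
    )


def confusion_metrics(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> tuple[float, float, float, float]:
    """(ACC, precision, recall, F-measure) at a score threshold.

    A row is called positive when its score is >= threshold.  Precision is
    0 when nothing is called positive; F = 2PR/(P+R), 0 when P + R = 0.
    """
    labels = _check_binary(np.asarray(labels))
    scores = np.asarray(scores, dtype=float)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    acc = float((pred == labels).mean())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return acc, precision, recall, f


def stratified_kfold(labels: Sequence[int], k: int, seed: int) -> list[np.ndarray]:
    """k disjoint index folds with per-class sizes differing by <= 1.

    Within each class the indices are shuffled by ``seed`` and dealt
    round-robin to the folds.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise MetricError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in sorted(np.unique(labels)):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise MetricError(f"class {cls} has {len(idx)} members, fewer than k={k}")
        for pos, i in enumerate(rng.permutation(idx)):
            folds[pos % k].append(int(i))
    return [np.sort(np.array(f)) for f in folds]


@dataclass
class CVReport:
    """Outcome of repeated stratified k-fold cross-validation.

    ``per_repeat`` holds one row of pooled-held-out metrics per repeat;
    ``per_fold`` one row per (repeat, fold); ``aggregate`` maps each metric
    to its mean and standard deviation over repeats.
    """

    protocol: dict
    per_repeat: list[dict] = field(default_factory=list)
    per_fold: list[dict] = field(default_factory=list)
    aggregate: dict = field(default_factory=dict)

    def mean(self, metric: str) -> float:
        return self.aggregate[metric]["mean"]

    def to_dict(self) -> dict:
        return asdict(self)

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def cross_validate(
    X: np.ndarray,
    y: Sequence[int],
    params: BoostParams | None = None,
    k: int = 5,
    repeats: int = 50,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> CVReport:
    """Repeated stratified k-fold cross-validation of the boosted learner.

    Each repeat r draws a fresh stratified partition from seed + r, trains
    on k-1 folds, scores the held-out fold, pools the held-out scores of
    the repeat, and computes AUC/ACC/precision/recall/F on the pooled
    scores.  Aggregates are means and standard deviations over repeats.
    """
    params = params or BoostParams()
    X = np.asarray(X, dtype=float)
    y = _check_binary(np.asarray(y))
    report = CVReport(
        protocol={
            "n_folds": k,
            "n_repeats": repeats,
            "seed": seed,
            "params": asdict(params),
        }
    )
    for r in range(repeats):
        folds = stratified_kfold(y, k, seed + r)
        pooled_scores = np.empty(len(y))
        for fold_no, test_idx in enumerate(folds):
            train_mask = np.ones(len(y), dtype=bool)
            train_mask[test_idx] = False
            model = fit(X[train_mask], y[train_mask], params, feature_names)
            scores = predict(model, X[test_idx])
            pooled_scores[test_idx] = scores
            acc, prec, rec, f = confusion_metrics(scores, y[test_idx])
            report.per_fold.append(
                {
                    "repeat": r,
                    "fold": fold_no,
                    "auc": roc_auc(scores, y[test_idx]),
                    "acc": acc,
                    "precision": prec,
                    "recall": rec,
                    "f_measure": f,
                }
            )
        acc, prec, rec, f = confusion_metrics(pooled_scores, y)
        report.per_repeat.append(
            {
                "repeat": r,
                "auc": roc_auc(pooled_scores, y),
                "acc": acc,
                "precision": prec,
                "recall": rec,
                "f_measure": f,
            }
        )
    for m in METRICS:
        vals = np.array([row[m] for row in report.per_repeat])
        report.aggregate[m] = {"mean": float(vals.mean()), "std": float(vals.std())}
    return report


SCANNABLE = ("gamma", "lam", "max_depth", "n_rounds")


def scan(
    X: np.ndarray,
    y: Sequence[int],
    param_name: str,
    values: Iterable,
    base_params: BoostParams | None = None,
    k: int = 5,
    repeats: int = 5,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> pd.DataFrame:
    """Cross-validate along a grid over one hyperparameter.

    The remaining hyperparameters stay at ``base_params``; one row of mean
    metrics per grid value.
    """
    if param_name not in SCANNABLE:
        raise MetricError(f"can only scan one of {SCANNABLE}, not {param_name!r}")
    values = list(values)
    if not values:
        raise MetricError("empty parameter grid")
    base_params = base_params or BoostParams()
    rows = []
    for v in values:
        cast = int(v) if param_name in ("max_depth", "n_rounds") else float(v)
        params = BoostParams(**{**asdict(base_params), param_name: cast})
        rep = cross_validate(X, y, params, k=k, repeats=repeats, seed=seed,
                             feature_names=feature_names)
        rows.append(
            {
                param_name: cast,
                "mean_auc": rep.mean("auc"),
                "mean_acc": rep.mean("acc"),
                "mean_f_measure": rep.mean("f_measure"),
            }
        )
    return pd.DataFrame(rows)
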