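"""Regularized gradient-boosted regression trees, written from scratch.

The learner fits an additive ensemble of binary regression trees to the
logistic loss by Newton boosting: at round t the loss is expanded to
second order around the current raw scores, giving per-sample gradients
g_i = p_i - y_i and Hessians h_i = p_i (1 - p_i).  For a fixed tree
structure with leaf sample sets I_j, the optimal leaf weight is

    w_j* = - (sum_{i in I_j} g_i) / (sum_{i in I_j} h_i + lambda)

and the reduction in the regularized objective from splitting one leaf
into left/right children is

    gain = 1/2 [ G_L^2/(H_L + lambda) + G_R^2/(H_R + lambda)
                 - (G_L + G_R)^2/(H_L + H_R + lambda) ] - gamma

with lambda the L2 penalty on leaf weights and gamma the per-leaf
complexity charge.  Trees are grown depth-first by exact greedy split
search over all features and all midpoints between consecutive distinct
values.  Predictions pass the accumulated raw score through the logistic
function, so the model scores class-1 (essential) probability.

Everything here is deterministic: ties in the split search resolve to the
lowest feature index, then the lowest threshold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np

__all__ = [
    "BoostParams",
    "RegressionTree",
    "BoostedEnsemble",
    "ModelError",
    "logistic_grad_hess",
    "leaf_weight",
    "split_gain",
    "find_best_split",
    "fit",
    "predict",
    "predict_raw",
    "feature_importance",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


class ModelError(ValueError):
    """Invalid model input, file, or training data."""


@dataclass(frozen=True)
class BoostParams:
    """Training hyperparameters.

    n_rounds is the number of boosting iterations (the ensemble size T),
    max_depth the maximum tree depth K (0 collapses each tree to a single
    leaf), gamma the per-leaf penalty, lam the L2 penalty on leaf weights,
    eta the shrinkage applied to every tree's contribution, and
    min_child_hessian the minimum summed Hessian allowed in a child.  The
    defaults are the settings the method was tuned to: gamma 0, lam 1.0,
    depth 6, 1000 rounds.
    """

    n_rounds: int = 1000
    max_depth: int = 6
    gamma: float = 0.0
    lam: float = 1.0
    eta: float = 0.3
    min_child_hessian: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rounds < 1:
            raise ModelError("n_rounds must be >= 1")
        if self.max_depth < 0:
            raise ModelError("max_depth must be >= 0")
        if self.gamma < 0 or self.lam < 0 or self.min_child_hessian < 0:
            raise ModelError("gamma, lam and min_child_hessian must be >= 0")
        if not (0 < self.eta <= 1):
            raise ModelError("eta must lie in (0, 1]")


@dataclass
class RegressionTree:
    """One regression tree as a nested node dictionary.

    Internal nodes: {"feature": int, "threshold": float, "gain": float,
    "left": node, "right": node}; leaves: {"weight": float}.  Samples with
    feature value <= threshold go left.
    """

    root: dict[str, Any]

    @property
    def n_leaves(self) -> int:
        def count(node: dict[str, Any]) -> int:
            if "weight" in node:
                return 1
            return count(node["left"]) + count(node["right"])

        return count(self.root)

    def predict_weight(self, X: np.ndarray) -> np.ndarray:
        """Leaf weight assigned to each row of ``X`` (the mapping q)."""
        out = np.empty(len(X))
        for i, row in enumerate(X):
            node = self.root
            while "weight" not in node:
                node = node["left"] if row[node["feature"]] <= node["threshold"] else node["right"]
            out[i] = node["weight"]
        return out

    def iter_splits(self):
        """Yield (feature, threshold, gain) for every internal node."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            if "weight" in node:
                continue
            yield node["feature"], node["threshold"], node["gain"]
            stack.append(node["right"])
            stack.append(node["left"])


@dataclass
class BoostedEnsemble:
    """A fitted boosted-tree model."""

    trees: list[RegressionTree]
    params: BoostParams
    feature_names: list[str]
    base_raw_score: float = 0.0
    #: optional per-round training trace: list (per tree) of split records
    #: {"feature", "threshold", "gain", "sample_idx"}; kept only when fit
    #: is asked to collect it
    trace: list[list[dict[str, Any]]] | None = field(default=None, repr=False)


def logistic_grad_hess(y: np.ndarray, raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gradient and Hessian of the logistic loss at raw score ``raw``.

    With p = sigmoid(raw): g = p - y, h = p (1 - p).
    """
    y = np.asarray(y, dtype=float)
    raw = np.asarray(raw, dtype=float)
    p = _sigmoid(raw)
    return p - y, p * (1.0 - p)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def leaf_weight(G: float, H: float, lam: float) -> float:
    """Optimal leaf weight -G / (H + lambda)."""
    if H + lam <= 0:
        raise ModelError("leaf weight undefined: H + lambda must be positive")
    return -G / (H + lam)


def split_gain(GL: float, HL: float, GR: float, HR: float, lam: float, gamma: float) -> float:
    """Objective reduction from splitting a leaf into (L, R) children."""
    if HL + lam <= 0 or HR + lam <= 0:
        raise ModelError("split gain undefined: child H + lambda must be positive")
    return 0.5 * (
        GL * GL / (HL + lam)
        + GR * GR / (HR + lam)
        - (GL + GR) ** 2 / (HL + HR + lam)
    ) - gamma


def find_best_split(
    X: np.ndarray,
    g: np.ndarray,
    h: np.ndarray,
    lam: float,
    gamma: float,
    min_child_hessian: float = 0.0,
) -> tuple[int, float, float] | None:
    """Exact greedy split search over all features and midpoints.

    Returns (feature, threshold, gain) maximizing the split gain, or None
    when no candidate has strictly positive gain.  Candidate thresholds are
    midpoints between consecutive distinct sorted values; both children
    must carry a summed Hessian >= ``min_child_hessian``.  Ties resolve to
    the lowest feature index, then the lowest threshold.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if n < 2:
        return None
    order = np.argsort(X, axis=0, kind="stable")
    Xs = np.take_along_axis(X, order, axis=0)
    Gs = np.cumsum(g[order], axis=0)
    Hs = np.cumsum(h[order], axis=0)
    Gt, Ht = Gs[-1], Hs[-1]

    GL, HL = Gs[:-1], Hs[:-1]  # prefix sums: split after position p
    GR, HR = Gt - GL, Ht - HL
    with np.errstate(divide="ignore", invalid="ignore"):
        gains = 0.5 * (GL**2 / (HL + lam) + GR**2 / (HR + lam) - Gt**2 / (Ht + lam)) - gamma
    valid = (
        (Xs[:-1] < Xs[1:])
        & (HL >= min_child_hessian)
        & (HR >= min_child_hessian)
        & np.isfinite(gains)  # guards lam = 0 with a zero-Hessian child
    )
    gains = np.where(valid, gains, -np.inf)

    best_per_feature = gains.max(axis=0)
    best_feature = int(np.argmax(best_per_feature))  # first max = lowest index
    best_gain = best_per_feature[best_feature]
    if not np.isfinite(best_gain) or best_gain <= 0:
        return None
    p = int(np.argmax(gains[:, best_feature]))  # first max = lowest threshold
    lo, hi = Xs[p, best_feature], Xs[p + 1, best_feature]
    threshold = (lo + hi) / 2.0
    if threshold >= hi:  # midpoint rounded up between adjacent floats
        threshold = lo
    return best_feature, float(threshold), float(best_gain)


def _grow_tree(
    X: np.ndarray,
    g: np.ndarray,
    h: np.ndarray,
    params: BoostParams,
    trace: list[dict[str, Any]] | None,
) -> RegressionTree:
    def build(idx: np.ndarray, depth: int) -> dict[str, Any]:
        G, H = float(g[idx].sum()), float(h[idx].sum())
        if depth >= params.max_depth or idx.size < 2:
            return {"weight": leaf_weight(G, H, params.lam)}
        found = find_best_split(
            X[idx], g[idx], h[idx], params.lam, params.gamma, params.min_child_hessian
        )
        if found is None:
            return {"weight": leaf_weight(G, H, params.lam)}
        feature, threshold, gain = found
        if trace is not None:
            trace.append(
                {"feature": feature, "threshold": threshold, "gain": gain,
                 "sample_idx": idx.copy()}
            )
        left = idx[X[idx, feature] <= threshold]
        right = idx[X[idx, feature] > threshold]
        return {
            "feature": feature,
            "threshold": threshold,
            "gain": gain,
            "left": build(left, depth + 1),
            "right": build(right, depth + 1),
        }

    return RegressionTree(build(np.arange(len(X)), 0))


def fit(
    X: np.ndarray,
    y: np.ndarray,
    params: BoostParams | None = None,
    feature_names: list[str] | None = None,
    collect_trace: bool = False,
) -> BoostedEnsemble:
    """Train a boosted ensemble on a binary-labelled training set.

    The raw score starts at 0; each round computes logistic gradients and
    Hessians at the current scores, grows one tree by exact greedy search,
    assigns optimal leaf weights, and advances the scores by eta times the
    new tree.  Fully deterministic for fixed inputs.
    """
    params = params or BoostParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ModelError("X must be 2-D with one row per label")
    if np.isnan(X).any():
        raise ModelError("training matrix contains NaN")
    if not set(np.unique(y)) <= {0, 1}:
        raise ModelError("labels must be 0/1")
    if len(np.unique(y)) < 2:
        raise ModelError("training needs both classes present")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    if len(feature_names) != X.shape[1]:
        raise ModelError("feature_names length does not match X")

    raw = np.zeros(len(y))
    trees: list[RegressionTree] = []
    traces: list[list[dict[str, Any]]] = []
    for _ in range(params.n_rounds):
        g, h = logistic_grad_hess(y, raw)
        tree_trace: list[dict[str, Any]] | None = [] if collect_trace else None
        tree = _grow_tree(X, g, h, params, tree_trace)
        raw = raw + params.eta * tree.predict_weight(X)
        trees.append(tree)
        if collect_trace:
            traces.append(tree_trace)  # type: ignore[arg-type]
    return BoostedEnsemble(
        trees=trees,
        params=params,
        feature_names=list(feature_names),
        base_raw_score=0.0,
        trace=traces if collect_trace else None,
    )


def predict_raw(model: BoostedEnsemble, X: np.ndarray) -> np.ndarray:
    """Accumulated raw (pre-logistic) score for each row."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.feature_names):
        raise ModelError(
            f"expected {len(model.feature_names)} feature columns, got {X.shape}"
        )
    raw = np.full(len(X), model.base_raw_score)
    for tree in model.trees:
        raw += model.params.eta * tree.predict_weight(X)
    return raw


def predict(model: BoostedEnsemble, X: np.ndarray) -> np.ndarray:
    """Class-1 probability for each row of ``X``."""
    return _sigmoid(predict_raw(model, X))


def feature_importance(model: BoostedEnsemble) -> dict[str, float]:
    """Gain-based relative importance, normalized to sum to 1.

    Each split credits its gain to the feature it tests; features never
    split on score 0.
    """
    totals = np.zeros(len(model.feature_names))
    for tree in model.trees:
        for feature, _, gain in tree.iter_splits():
            totals[feature] += gain
    s = totals.sum()
    if s <= 0:
        warnings.warn("model has no splits; importances are all zero")
        return dict(zip(model.feature_names, np.zeros_like(totals)))
    return dict(zip(model.feature_names, totals / s))


def save_model(model: BoostedEnsemble, path: str | Path) -> None:
    """Serialize a model to versioned JSON (trace is not persisted)."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "params": asdict(model.params),
        "base_raw_score": model.base_raw_score,
        "feature_names": model.feature_names,
        "trees": [t.root for t in model.trees],
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> BoostedEnsemble:
    """Load a model saved by :func:`save_model`."""
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelError(f"{path}: not a model file")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelError(
            f"{path}: unsupported model format {payload['format_version']}"
        )
    try:
        return BoostedEnsemble(
            trees=[RegressionTree(root) for root in payload["trees"]],
            params=BoostParams(**payload["params"]),
            feature_names=list(payload["feature_names"]),
            base_raw_score=float(payload["base_raw_score"]),
        )
    except (KeyError, TypeError) as exc:
        raise ModelError(f"{path}: corrupt model file: {exc}") from exc
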