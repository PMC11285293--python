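"""Gradient-boosted decision stumps and baseline classifiers.

The final oncogenicity predictor is an additive ensemble of depth-1 trees
(stumps) trained on the logistic loss with second-order (Newton) boosting:
per round, gradients g_i = p_i - y_i and hessians h_i = p_i (1 - p_i) are
computed from the current margins, a single stump is grown by exhaustive
exact-greedy split search maximising

    gain = 1/2 [ G_L^2/(H_L+lambda) + G_R^2/(H_R+lambda)
                 - (G_L+G_R)^2/(H_L+H_R+lambda) ] - gamma,

and the leaf weights w = -G/(H+lambda), damped by the learning rate eta, are
added to the margins.  Training is fully deterministic: ties in the split
search are broken by lowest feature index, then lowest threshold.

Estimators follow the scikit-learn protocol (``fit`` / ``predict_proba`` /
``get_params``) so they compose with sklearn model-selection utilities,
but the boosting algorithm itself is implemented here from scratch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ShapeError

__all__ = [
    "Stump",
    "fit_stump",
    "StumpBoostingClassifier",
    "GiniTreeClassifier",
    "train",
    "score_baseline",
    "confidence_percent",
    "render_prediction",
]


@dataclass(frozen=True)
class Stump:
    """One depth-1 tree: rows with feature value < threshold go left."""

    feature_index: int
    threshold: float
    left_weight: float
    right_weight: float

    def contributions(self, X: np.ndarray) -> np.ndarray:
        go_left = X[:, self.feature_index] < self.threshold
        return np.where(go_left, self.left_weight, self.right_weight)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def fit_stump(
    X: np.ndarray,
    gradients: np.ndarray,
    hessians: np.ndarray,
    lambda_: float = 1.0,
    gamma_: float = 0.0,
) -> Stump | None:
    """Exact-greedy single-split search on gradient/hessian statistics.

    Returns ``None`` when no split has strictly positive gain.  Thresholds
    are midpoints between consecutive distinct sorted feature values;
    constant features are skipped.
    """
    X = np.asarray(X, dtype=float)
    g = np.asarray(gradients, dtype=float)
    h = np.asarray(hessians, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("fit_stump requires a non-empty 2-D matrix")
    if g.shape[0] != X.shape[0] or h.shape[0] != X.shape[0]:
        raise ValueError("gradients/hessians must match the number of rows")
    if np.any(h < 0):
        raise ValueError("hessians must be non-negative")

    G, H = g.sum(), h.sum()
    parent = G * G / (H + lambda_)

    best_gain = 0.0
    best: tuple[int, float, float, float] | None = None
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        cg = np.cumsum(g[order])
        ch = np.cumsum(h[order])
        # candidate split after position i (0-based) where value changes
        change = np.nonzero(np.diff(xs) > 0)[0]
        if change.size == 0:
            continue
        GL, HL = cg[change], ch[change]
        GR, HR = G - GL, H - HL
        gain = 0.5 * (GL * GL / (HL + lambda_) + GR * GR / (HR + lambda_) - parent) - gamma_
        k = int(np.argmax(gain))
        # tie-break inside a feature: argmax takes the first (lowest threshold)
        ties = np.nonzero(gain == gain[k])[0]
        k = int(ties[0])
        if gain[k] > best_gain:
            best_gain = float(gain[k])
            thr = 0.5 * (xs[change[k]] + xs[change[k] + 1])
            wl = -GL[k] / (HL[k] + lambda_)
            wr = -GR[k] / (HR[k] + lambda_)
            best = (j, float(thr), float(wl), float(wr))
    if best is None:
        return None
    return Stump(*best)


class StumpBoostingClassifier(ClassifierMixin, BaseEstimator):
    """Second-order gradient boosting restricted to depth-1 trees.

    Parameters
    ----------
    n_rounds : int
        Maximum number of boosting rounds (stumps).  Boosting stops early
        when no split with positive gain exists.
    eta : float
        Learning rate applied to every leaf weight.
    lambda_ : float
        L2 regularisation of leaf weights.
    gamma_ : float
        Minimum gain required to keep a split.

    Attributes
    ----------
    base_score_ : float
        Log-odds of the positive-class frequency of the training labels.
    stumps_ : list of Stump
        Ordered fitted stumps; may be shorter than ``n_rounds``.
    """

    def __init__(self, n_rounds: int = 15, eta: float = 0.3,
                 lambda_: float = 1.0, gamma_: float = 0.0):
        self.n_rounds = n_rounds
        self.eta = eta
        self.lambda_ = lambda_
        self.gamma_ = gamma_

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        uniq = np.unique(y)
        if not np.isin(uniq, [0, 1]).all():
            raise ValueError("labels must be binary 0/1")
        y = y.astype(float)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]

        # canonical internal row order: makes training bit-exactly invariant
        # to row permutation (summation order of tied feature values is fixed)
        order = np.lexsort(tuple(X[:, j] for j in range(X.shape[1] - 1, -1, -1)) + (y,))
        X, y = X[order], y[order]

        p0 = float(y.mean())
        if p0 in (0.0, 1.0):
            warnings.warn("single-class training labels; fitting base score only")
            # clamp so the log-odds stay finite
            eps = 1.0 / (2.0 * max(len(y), 1))
            p0 = min(max(p0, eps), 1.0 - eps)
            self.base_score_ = float(np.log(p0 / (1.0 - p0)))
            self.stumps_ = []
            return self

        self.base_score_ = float(np.log(p0 / (1.0 - p0)))
        margins = np.full(X.shape[0], self.base_score_)
        stumps: list[Stump] = []
        for _ in range(self.n_rounds):
            p = _sigmoid(margins)
            g = p - y
            h = p * (1.0 - p)
            stump = fit_stump(X, g, h, self.lambda_, self.gamma_)
            if stump is None:
                break
            stumps.append(stump)
            margins = margins + self.eta * stump.contributions(X)
        self.stumps_ = stumps
        return self

    def _check_X(self, X) -> np.ndarray:
        check_is_fitted(self, "stumps_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ShapeError(
                f"expected {self.n_features_in_} feature columns, got "
                f"{X.shape[1] if X.ndim == 2 else 'non-2D input'}"
            )
        return X

    def decision_function(self, X) -> np.ndarray:
        """Raw additive margins (log-odds scale)."""
        X = self._check_X(X)
        margins = np.full(X.shape[0], self.base_score_)
        for stump in self.stumps_:
            margins += self.eta * stump.contributions(X)
        return margins

    def predict_proba(self, X) -> np.ndarray:
        p = _sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


def train(X, y, params: dict | None = None) -> StumpBoostingClassifier:
    """Functional wrapper: fit a :class:`StumpBoostingClassifier`."""
    return StumpBoostingClassifier(**(params or {})).fit(X, y)


@dataclass
class _TreeNode:
    feature_index: int | None = None
    threshold: float = 0.0
    left: "_TreeNode | None" = None
    right: "_TreeNode | None" = None
    value: float = 0.5  # positive-class frequency at the leaf


class GiniTreeClassifier(ClassifierMixin, BaseEstimator):
    """Greedy CART-style tree with Gini impurity, used as a baseline.

    Exhaustive midpoint thresholds, deterministic tie-breaking (lowest
    feature index, then lowest threshold); leaves emit the positive-class
    frequency.
    """

    def __init__(self, depth: int = 1):
        self.depth = depth

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if X.ndim != 2 or y.shape[0] != X.shape[0] or X.shape[0] == 0:
            raise ValueError("invalid training data")
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        self.tree_ = self._grow(X, y, self.depth)
        return self

    @staticmethod
    def _best_gini_split(X, y):
        n = len(y)
        parent_pos = y.sum()
        best = None
        best_impurity = None
        for j in range(X.shape[1]):
            order = np.argsort(X[:, j], kind="stable")
            xs = X[order, j]
            cpos = np.cumsum(y[order])
            change = np.nonzero(np.diff(xs) > 0)[0]
            if change.size == 0:
                continue
            nl = change + 1.0
            nr = n - nl
            pl = cpos[change] / nl
            pr = (parent_pos - cpos[change]) / nr
            impurity = nl * 2 * pl * (1 - pl) + nr * 2 * pr * (1 - pr)
            k = int(np.nonzero(impurity == impurity.min())[0][0])
            if best_impurity is None or impurity[k] < best_impurity:
                best_impurity = float(impurity[k])
                best = (j, 0.5 * (xs[change[k]] + xs[change[k] + 1]))
        if best is None:
            return None
        parent_impurity = n * 2 * (parent_pos / n) * (1 - parent_pos / n)
        if best_impurity >= parent_impurity:
            return None
        return best

    def _grow(self, X, y, depth) -> _TreeNode:
        node = _TreeNode(value=float(y.mean()))
        if depth == 0 or y.min() == y.max():
            return node
        split = self._best_gini_split(X, y)
        if split is None:
            return node
        j, thr = split
        mask = X[:, j] < thr
        node.feature_index = j
        node.threshold = float(thr)
        node.left = self._grow(X[mask], y[mask], depth - 1)
        node.right = self._grow(X[~mask], y[~mask], depth - 1)
        return node

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "tree_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ShapeError(f"expected {self.n_features_in_} feature columns")
        p = np.empty(X.shape[0])
        for i, row in enumerate(X):
            node = self.tree_
            while node.feature_index is not None:
                node = node.left if row[node.feature_index] < node.threshold else node.right
            p[i] = node.value
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def score_baseline(values, orientation: str = "higher-is-oncogenic") -> np.ndarray:
    """Use a single feature directly as a ranking score (no fitting)."""
    values = np.asarray(values, dtype=float)
    if orientation == "higher-is-oncogenic":
        return values.copy()
    if orientation == "lower-is-oncogenic":
        return -values
    raise ValueError(
        "orientation must be 'higher-is-oncogenic' or 'lower-is-oncogenic'"
    )


def confidence_percent(p: float) -> int:
    """Percent confidence of the predicted class: round(100*max(p, 1-p)).

    Rounds half up with a tiny guard so decimal boundaries (e.g. p = 0.995,
    which prints as 100%) are not lost to binary float representation.
    """
    return int(np.floor(100.0 * max(p, 1.0 - p) + 0.5 + 1e-9))


def render_prediction(p: float) -> str:
    """Human-readable call: 'oncogenic'/'neutral' with percent confidence.

    p > 0.5 calls oncogenic; exactly 0.5 is reported as neutral.
    """
    label = "oncogenic" if p > 0.5 else "neutral"
    return f"{label}, {confidence_percent(p)}% confidence"
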