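"""Evaluation protocol: grouped splits, ROC/PR metrics, bootstrap, curve bands.

The train/test split and the 5-fold cross-validation are *grouped* by
(protein, position): every row sharing a group key lands on the same side,
so no mutated position seen in training reappears at test time.  Metric
uncertainty is summarised by bootstrapping rows with replacement (N=1000 by
default); ROC/PR curves from repeated runs are aggregated by interpolating
each curve onto a fixed 30-point grid and reporting the pointwise median and
the 10%/90% quantiles.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boosting import StumpBoostingClassifier

__all__ = [
    "GroupedSplit",
    "CurveSet",
    "MetricSummary",
    "grouped_split",
    "grouped_kfold",
    "roc_points",
    "roc_auc",
    "pr_points",
    "average_precision",
    "bootstrap_metric",
    "aggregate_curves",
    "model_selection",
    "robustness_runs",
]

logger = logging.getLogger(__name__)


@dataclass
class GroupedSplit:
    train_idx: np.ndarray
    test_idx: np.ndarray

    def __post_init__(self):
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError("train and test indices overlap")


def _group_index(groups) -> dict:
    table: dict = {}
    for i, g in enumerate(groups):
        table.setdefault(g, []).append(i)
    return table


def grouped_split(groups, test_frac: float = 0.2, seed: int = 0) -> GroupedSplit:
    """Random train/test split that never separates rows of one group.

    Groups are shuffled with a seeded generator and accumulated into the
    test side until it reaches ``test_frac`` of the rows (within one group).
    """
    table = _group_index(list(groups))
    if len(table) < 2:
        raise ValueError("need at least two distinct groups to split")
    keys = sorted(table.keys())
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    n = sum(len(v) for v in table.values())
    target = test_frac * n
    test: list[int] = []
    taken: list = []
    for key in keys:
        if len(test) >= target:
            break
        test.extend(table[key])
        taken.append(key)
    test_set = set(test)
    train = [i for i in range(n) if i not in test_set]
    if not train:
        # one dominant group swallowed everything: return it to the train side
        last = set(table[taken[-1]])
        train = sorted(test_set & last)
        test = sorted(test_set - last)
    return GroupedSplit(train_idx=np.array(sorted(train)), test_idx=np.array(sorted(test)))


def grouped_kfold(groups, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """k disjoint folds of row indices, each group wholly inside one fold.

    Groups are shuffled, then assigned largest-first to the currently
    smallest fold, which balances fold sizes at least as well as naive
    round-robin assignment.
    """
    table = _group_index(list(groups))
    if k > len(table):
        raise ValueError(f"k={k} exceeds the number of distinct groups ({len(table)})")
    keys = sorted(table.keys())
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    keys.sort(key=lambda g: -len(table[g]))  # stable: ties keep shuffled order
    folds: list[list[int]] = [[] for _ in range(k)]
    sizes = np.zeros(k, dtype=int)
    for key in keys:
        j = int(np.argmin(sizes))
        folds[j].extend(table[key])
        sizes[j] += len(table[key])
    return [np.array(sorted(f)) for f in folds]


def _check_binary(labels) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if not np.isin(labels, [0, 1]).all():
        raise ValueError("labels must be binary 0/1")
    return labels


def roc_points(labels, scores) -> np.ndarray:
    """(FPR, TPR) points from (0,0) to (1,1), one step per distinct score."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # indices where the next score differs: threshold step boundaries
    distinct = np.nonzero(np.diff(s))[0]
    steps = np.append(distinct, len(s) - 1)
    tp = np.cumsum(y)[steps]
    fp = steps + 1 - tp
    fpr = np.concatenate([[0.0], fp / n_neg])
    tpr = np.concatenate([[0.0], tp / n_pos])
    return np.column_stack([fpr, tpr])


def roc_auc(labels, scores) -> float:
    """Area under the ROC curve by the trapezoid rule over tie-grouped steps."""
    pts = roc_points(labels, scores)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def pr_points(labels, scores) -> np.ndarray:
    """(recall, precision) per descending threshold, padded at recall 0.

    The recall-0 point carries the precision of the highest-score threshold
    so curves can be interpolated down to the origin of the recall axis.
    """
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = labels.sum()
    if n_pos == 0:
        raise ValueError("PR curve requires at least one positive")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    distinct = np.nonzero(np.diff(s))[0]
    steps = np.append(distinct, len(s) - 1)
    tp = np.cumsum(y)[steps]
    recall = tp / n_pos
    precision = tp / (steps + 1)
    recall = np.concatenate([[0.0], recall])
    precision = np.concatenate([[precision[0]], precision])
    return np.column_stack([recall, precision])


def average_precision(labels, scores) -> float:
    """AP = sum over thresholds of (R_n - R_{n-1}) * P_n."""
    pts = pr_points(labels, scores)
    recall, precision = pts[:, 0], pts[:, 1]
    return float(np.sum(np.diff(recall) * precision[1:]))


METRICS = {"roc_auc": roc_auc, "average_precision": average_precision}


@dataclass
class MetricSummary:
    point_estimate: float
    bootstrap_mean: float
    bootstrap_sd: float
    n_boot: int
    n_redrawn: int = 0


def bootstrap_metric(labels, scores, metric: str = "roc_auc",
                     n_boot: int = 1000, seed: int = 0) -> MetricSummary:
    """Bootstrap mean/sd of a ranking metric over row resamples.

    Resamples containing a single class are redrawn (and counted) so that
    exactly ``n_boot`` usable resamples contribute.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {sorted(METRICS)}")
    fn = METRICS[metric]
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    point = fn(labels, scores)
    rng = np.random.default_rng(seed)
    n = len(labels)
    values = np.empty(n_boot)
    redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            yb = labels[idx]
            if 0 < yb.sum() < n:
                break
            redrawn += 1
        values[b] = fn(yb, scores[idx])
    if redrawn:
        logger.info("redrew %d degenerate bootstrap resamples", redrawn)
    return MetricSummary(
        point_estimate=point,
        bootstrap_mean=float(values.mean()),
        bootstrap_sd=float(values.std(ddof=1)),
        n_boot=n_boot,
        n_redrawn=redrawn,
    )


@dataclass
class CurveSet:
    """Per-iteration curves aggregated on a fixed grid with quantile bands."""

    grid: np.ndarray
    median: np.ndarray
    q10: np.ndarray
    q90: np.ndarray
    interpolated: np.ndarray = field(repr=False, default=None)


def aggregate_curves(curves, grid_size: int = 30) -> CurveSet:
    """Interpolate each (x, y) curve onto a fixed grid; quantile bands.

    Each curve is padded to x=0 and x=1 with its endpoint y values, then
    linearly interpolated onto ``grid_size`` evenly spaced grid points in
    [0, 1].  Pointwise 10%, 50% and 90% empirical quantiles use linear
    interpolation between order statistics.
    """
    if not curves:
        raise ValueError("need at least one curve")
    grid = np.linspace(0.0, 1.0, grid_size)
    rows = []
    for x, y in ((np.asarray(c[0], float), np.asarray(c[1], float)) for c in curves):
        if len(x) < 2 or len(x) != len(y):
            raise ValueError("each curve needs >= 2 (x, y) points")
        if np.any(np.diff(x) < 0):
            raise ValueError("curve x values must be non-decreasing")
        if x.min() < -1e-12 or x.max() > 1 + 1e-12:
            raise ValueError("curve x values must lie in [0, 1]")
        rows.append(np.interp(grid, x, y))  # np.interp pads with endpoint y
    interp = np.vstack(rows)
    q10, med, q90 = np.quantile(interp, [0.10, 0.50, 0.90], axis=0)
    return CurveSet(grid=grid, median=med, q10=q10, q90=q90, interpolated=interp)


def model_selection(X, y, groups, grid: dict, k: int = 5, seed: int = 0,
                    estimator_factory=StumpBoostingClassifier):
    """Grid search by mean grouped-k-fold ROC AUC.

    ``grid`` maps parameter names to candidate lists.  Folds whose
    validation side is single-class are skipped with a warning; a grid cell
    with no usable fold is excluded.  Ties are broken by fewest boosting
    rounds, then smallest learning rate, then grid order.

    Returns (best_params, table) where table is a DataFrame with one row
    per grid cell and its mean validation AUC.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("hyperparameter grid must be non-empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    folds = grouped_kfold(groups, k=k, seed=seed)
    all_idx = np.arange(len(y))
    names = list(grid.keys())
    records = []
    for combo in itertools.product(*(grid[n] for n in names)):
        params = dict(zip(names, combo))
        aucs = []
        for fold in folds:
            val = fold
            train = np.setdiff1d(all_idx, val)
            if len(np.unique(y[val])) < 2 or len(np.unique(y[train])) < 2:
                warnings.warn("skipping single-class fold during model selection")
                continue
            model = estimator_factory(**params).fit(X[train], y[train])
            aucs.append(roc_auc(y[val], model.predict_proba(X[val])[:, 1]))
        if aucs:
            records.append({**params, "mean_auc": float(np.mean(aucs)), "n_folds": len(aucs)})
    if not records:
        raise ValueError("every grid cell was excluded (all folds degenerate)")
    table = pd.DataFrame.from_records(records)
    best = max(
        range(len(records)),
        key=lambda i: (
            records[i]["mean_auc"],
            -records[i].get("n_rounds", 0),
            -records[i].get("eta", 0.0),
            -i,
        ),
    )
    best_params = {n: records[best][n] for n in names}
    return best_params, table


def robustness_runs(pipeline, n_seeds: int = 100, base_seed: int = 0) -> pd.DataFrame:
    """Repeat a full (split, select, train, evaluate) closure over seeds.

    ``pipeline(seed)`` must return a mapping of metric name to value; the
    result is one row per seed.
    """
    records = []
    for s in range(n_seeds):
        metrics = pipeline(base_seed + s)
        records.append({"seed": base_seed + s, **metrics})
    return pd.DataFrame.from_records(records)
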