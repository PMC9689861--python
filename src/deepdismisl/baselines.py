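"""Comparator aggregators and the mean-feature penalized Cox baseline.

All neural comparators share the scorer, head, Cox loss and training loop
with the percentile model; only the aggregation of the n instance scores
into head features differs:

* ``meanpool``            — mean score (width 1)
* ``maxpool_top1``        — max score (width 1)
* ``maxpool_top10``       — 10 largest scores (width 10)
* ``mesonet_topbottom10`` — 10 largest + 10 smallest scores (width 20)

``meanfeature_lassocox`` is the non-neural comparator: the bag-level mean
feature vector fed to an L1-penalized Cox proportional-hazards fit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .bag_data import InstanceFeatureBag
from .percentile_mil import Aggregator, PercentileAggregator, PercentileScheme
from .survival_stats import concordance_index

__all__ = [
    "meanpool_features",
    "maxpool_topk_features",
    "top_bottom_k_features",
    "mean_feature_vector",
    "fit_penalized_cox",
    "PenalizedCoxModel",
    "MeanPoolAggregator",
    "MaxPoolTopKAggregator",
    "TopBottomKAggregator",
    "make_aggregator",
    "AGGREGATOR_NAMES",
]


def meanpool_features(scores) -> np.ndarray:
    """Mean instance score as a width-1 head feature."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty scores")
    return np.array([scores.mean()])


def maxpool_topk_features(scores, k: int) -> np.ndarray:
    """The k largest scores in descending order."""
    scores = np.asarray(scores, dtype=float)
    if not 1 <= k <= scores.size:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={scores.size}")
    return np.sort(scores)[::-1][:k]


def top_bottom_k_features(scores, k: int) -> np.ndarray:
    """k largest (descending) followed by k smallest (ascending) scores."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2 * k:
        raise ValueError(f"need n >= 2k, got n={scores.size}, k={k}")
    s = np.sort(scores)
    return np.concatenate([s[::-1][:k], s[:k]])


def mean_feature_vector(bag: InstanceFeatureBag) -> np.ndarray:
    """Column-wise mean of a bag's feature matrix (length d)."""
    return np.asarray(bag.features, dtype=float).mean(axis=0)


class PenalizedCoxModel:
    """Linear Cox risk model: risk = design @ coef."""

    def __init__(self, coef: np.ndarray, l1_strength: float):
        self.coef = np.asarray(coef, dtype=float)
        self.l1_strength = float(l1_strength)

    def predict_risk(self, design) -> np.ndarray:
        return np.asarray(design, dtype=float) @ self.coef


def fit_penalized_cox(
    design,
    times,
    events,
    l1_strength: float | None = None,
    cv_folds: int = 3,
    seed: int = 0,
) -> PenalizedCoxModel:
    """L1-penalized Cox proportional-hazards fit on bag-level features.

    When ``l1_strength`` is None the penalty is chosen by ``cv_folds``-fold
    cross-validation over a geometric grid, scored by the held-out
    concordance index.  Columns are standardized internally; coefficients
    are returned on the original feature scale.
    """
    X = np.asarray(design, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if X.ndim != 2 or X.shape[0] != times.size:
        raise ValueError("design rows must match labels")
    if events.sum() < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("degenerate design: all columns have zero variance")
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    def _fit(Xmat, t, e, penalty) -> np.ndarray:
        df = pd.DataFrame(Xmat, columns=[f"x{i}" for i in range(Xmat.shape[1])])
        df["time"] = t
        df["event"] = e
        cph = CoxPHFitter(penalizer=penalty, l1_ratio=1.0)
        cph.fit(df, duration_col="time", event_col="event")
        return cph.params_.to_numpy()

    if l1_strength is None:
        grid = np.geomspace(1e-3, 1.0, 7)
        rng = np.random.default_rng(seed)
        folds = rng.permutation(times.size) % cv_folds
        best = (None, -np.inf)
        for pen in grid:
            cs = []
            for f in range(cv_folds):
                tr, te = folds != f, folds == f
                if events[tr].sum() < 2 or events[te].sum() < 1:
                    continue
                beta = _fit(Xs[tr], times[tr], events[tr], pen)
                try:
                    cs.append(concordance_index(Xs[te] @ beta, times[te], events[te]))
                except ValueError:
                    continue
            score = np.mean(cs) if cs else -np.inf
            if score > best[1]:
                best = (pen, score)
        l1_strength = best[0] if best[0] is not None else float(grid[0])
    beta_std = _fit(Xs, times, events, float(l1_strength))
    coef = np.zeros(X.shape[1])
    coef[keep] = beta_std / sd[keep]
    return PenalizedCoxModel(coef, float(l1_strength))


# ---------------------------------------------------------------------------
# batched aggregators sharing the percentile model's interface
# ---------------------------------------------------------------------------


class MeanPoolAggregator(Aggregator):
    name = "meanpool"

    def output_width(self, n_instances: int) -> int:
        return 1

    def forward(self, scores: np.ndarray):
        return scores.mean(axis=1, keepdims=True), scores.shape[1]

    def backward(self, dfeats: np.ndarray, ctx) -> np.ndarray:
        n = ctx
        return np.repeat(dfeats / n, n, axis=1)


class MaxPoolTopKAggregator(Aggregator):
    def __init__(self, k: int):
        self.k = k
        self.name = "maxpool_top1" if k == 1 else f"maxpool_top{k}"

    def output_width(self, n_instances: int) -> int:
        return self.k

    def forward(self, scores: np.ndarray):
        order = np.argsort(-scores, kind="stable", axis=1)
        idx = order[:, : self.k]
        return np.take_along_axis(scores, idx, axis=1), (idx, scores.shape[1])

    def backward(self, dfeats: np.ndarray, ctx) -> np.ndarray:
        idx, n = ctx
        dscores = np.zeros((dfeats.shape[0], n))
        np.add.at(dscores, (np.arange(dfeats.shape[0])[:, None], idx), dfeats)
        return dscores


class TopBottomKAggregator(Aggregator):
    def __init__(self, k: int = 10):
        self.k = k
        self.name = f"mesonet_topbottom{k}"

    def output_width(self, n_instances: int) -> int:
        return 2 * self.k

    def forward(self, scores: np.ndarray):
        order = np.argsort(scores, kind="stable", axis=1)
        idx = np.concatenate([order[:, ::-1][:, : self.k], order[:, : self.k]], axis=1)
        return np.take_along_axis(scores, idx, axis=1), (idx, scores.shape[1])

    backward = MaxPoolTopKAggregator.backward


AGGREGATOR_NAMES = (
    "dismisl",
    "mesonet_topbottom10",
    "meanpool",
    "maxpool_top1",
    "maxpool_top10",
    "meanfeature_lassocox",
)


def make_aggregator(name: str, scheme: PercentileScheme | None = None) -> Aggregator:
    """Build an aggregator from its config-enum name."""
    if name == "dismisl":
        if scheme is None:
            raise ValueError("dismisl aggregator needs a percentile scheme")
        return PercentileAggregator(scheme)
    if name == "meanpool":
        return MeanPoolAggregator()
    if name == "maxpool_top1":
        return MaxPoolTopKAggregator(1)
    if name == "maxpool_top10":
        return MaxPoolTopKAggregator(10)
    if name == "mesonet_topbottom10":
        return TopBottomKAggregator(10)
    raise ValueError(f"unknown aggregator {name!r}")
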