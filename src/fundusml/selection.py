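"""Univariate and distance-aware feature ranking.

Three criteria score each feature column against the class labels:

* **KW** — the Kruskal–Wallis one-way ANOVA H statistic (rank-based, so
  invariant under strictly monotone transforms of a feature).
* **BW** — the ratio of between-category to within-category sum of
  squares, Σ_k n_k (x̄_k − x̄)² / Σ_k Σ_{i∈k} (x_i − x̄_k)²; invariant
  under affine transforms.  The denominator is floored at 1e−12 so a
  zero-within-variance feature gets a large finite score instead of a
  division error (effective ceiling: numerator / 1e−12).
* **MRMD** — max-relevance-max-distance: the magnitude of the Spearman
  rank correlation between feature and label (relevance) plus the mean
  Euclidean distance of the standardised feature column to all other
  standardised columns (redundancy-penalising distance).  Both
  components are scaled to [0, 1] by their maxima before the
  equally-weighted sum, since the raw distance term grows with √n.

Top-k subsets are nested by construction: the top-1024 features are a
subset of the top-2048, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from fundusml.datatypes import FeatureMatrix

METHODS = ("KW", "BW", "MRMD")
BW_DENOM_FLOOR = 1e-12


@dataclass
class FeatureRanking:
    """Per-feature scores and the induced decreasing-score order.

    Ties are broken toward the lower feature index, so ``order`` is a
    deterministic permutation of the feature indices.
    """

    method: str
    scores: np.ndarray
    order: np.ndarray

    def __post_init__(self) -> None:
        d = len(self.scores)
        if sorted(self.order.tolist()) != list(range(d)):
            raise ValueError("order must be a permutation of feature indices")


def _kw_scores(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    groups = [x[y == c] for c in np.unique(y)]
    d = x.shape[1]
    scores = np.empty(d)
    for j in range(d):
        cols = [g[:, j] for g in groups]
        if np.ptp(x[:, j]) == 0:
            scores[j] = 0.0  # constant feature carries no rank information
            continue
        try:
            scores[j] = stats.kruskal(*cols).statistic
        except ValueError:  # all values identical within the test
            scores[j] = 0.0
    return scores


def _bw_scores(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    grand = x.mean(axis=0)
    between = np.zeros(x.shape[1])
    within = np.zeros(x.shape[1])
    for c in classes:
        xc = x[y == c]
        mc = xc.mean(axis=0)
        between += len(xc) * (mc - grand) ** 2
        within += ((xc - mc) ** 2).sum(axis=0)
    return between / np.maximum(within, BW_DENOM_FLOOR)


def _mrmd_scores(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    n, d = x.shape
    # relevance: |Spearman rank correlation| with the class label
    rx = stats.rankdata(x, axis=0)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean(axis=0)
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum(axis=0) * (ryc**2).sum())
    denom[denom == 0] = 1.0
    relevance = np.abs(rxc.T @ ryc) / denom
    # distance: mean Euclidean distance between standardised columns,
    # via the Gram matrix to stay O(d² n) in one BLAS call
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    gram = z.T @ z
    sq = np.maximum(2.0 * n - 2.0 * gram, 0.0)
    dist = np.sqrt(sq)
    mean_dist = (dist.sum(axis=1) - np.diag(dist)) / max(d - 1, 1)
    for comp in (relevance, mean_dist):
        mx = comp.max()
        if mx > 0:
            comp /= mx
    return relevance + mean_dist


def rank_features(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    method: str = "KW",
) -> FeatureRanking:
    """Score every feature column and sort by decreasing score."""
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if isinstance(features, FeatureMatrix):
        x = features.values
        if labels is None:
            labels = features.labels
    else:
        x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain at least 2 classes")
    if method == "BW":
        counts = np.bincount(y)
        if (counts[counts > 0] < 2).any():
            raise ValueError("BW requires >= 2 samples per class")
    scorer = {"KW": _kw_scores, "BW": _bw_scores, "MRMD": _mrmd_scores}[method]
    scores = scorer(x, y)
    # stable sort on negated scores -> decreasing score, lower index first on ties
    order = np.argsort(-scores, kind="stable")
    return FeatureRanking(method=method, scores=scores, order=order)


def select_top_k(ranking: FeatureRanking, k: int) -> np.ndarray:
    """First k ranked feature indices, returned in original index order."""
    d = len(ranking.scores)
    if k > d:
        raise ValueError(f"k={k} exceeds feature count {d}")
    if k < 0:
        raise ValueError("k must be >= 0")
    return np.sort(ranking.order[:k])
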