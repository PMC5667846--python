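"""Clustering-and-voting classifier ensemble.

A pool of multiclass SVMs is built over a grid of decision schemes
(OVO / OVA / DAG) and RBF hyper-parameters (by default the 10 integer
values of log10 C and log10 σ in (−5, 5], i.e. 3 × 10 × 10 = 300
members).  Pool members are compared through a classifier distance
computed from their misclassification indicators on a held-out
evaluation split:

    Distance(C(i), C(j)) = 1 − (1 / 2m) Σ_k (d_ik Δ d_jk)

where d_ik ∈ {0, 1} flags member i mislabelling sample k and
d_ik Δ d_jk = d_ik + d_jk when *both* members err on sample k, else 0.
With 0/1 indicators the distance is 1 minus the fraction of samples both
members get wrong, and the diagonal equals 1 minus the member's own
error rate.

Affinity propagation (on similarity −distance, preference tuned by
bisection) groups the pool into a target number of clusters — seven by
default — and one representative per cluster enters the ensemble.  The
ensemble combines representative class-score matrices by fractional
voting:

    Y = (1 / n) Σ_i F_i · P_i

with per-member fractions F_i ∈ [0, 1] optimised on validation data by
deterministic coordinate ascent over the grid {0.0, 0.1, …, 1.0}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.cluster import AffinityPropagation

from fundusml.classifiers import BinaryLearnerSpec, MulticlassModel, train_multiclass
from fundusml.datatypes import FeatureMatrix

#: default log10 grid: the 10 integer values with −5 < log10(v) ≤ 5
DEFAULT_LOG_GRID: tuple[int, ...] = tuple(range(-4, 6))


class ClusterCountWarning(UserWarning):
    """Bisection could not reach the exact target exemplar count."""


@dataclass(frozen=True)
class GridSpec:
    """Scheme × log10(C) × log10(σ) grid defining the model pool."""

    schemes: tuple[str, ...] = ("OVO", "OVA", "DAG")
    logC_values: tuple[float, ...] = DEFAULT_LOG_GRID
    logSigma_values: tuple[float, ...] = DEFAULT_LOG_GRID

    def combinations(self) -> list[tuple[str, float, float]]:
        return [(s, lc, ls) for s, lc, ls in
                product(self.schemes, self.logC_values, self.logSigma_values)]

    def __len__(self) -> int:
        return len(self.schemes) * len(self.logC_values) * len(self.logSigma_values)


@dataclass
class ModelPool:
    """Trained grid members with predictions cached on an evaluation split."""

    members: list[MulticlassModel]
    coords: list[tuple[str, float, float]]
    pool_predictions: np.ndarray  # members × m predicted labels
    truth: np.ndarray  # m evaluation labels
    indicators: np.ndarray  # members × m, d_ik ∈ {0, 1}
    classes: np.ndarray

    @property
    def m(self) -> int:
        return len(self.truth)

    def member_accuracies(self) -> np.ndarray:
        return 1.0 - self.indicators.mean(axis=1)


@dataclass
class EnsembleModel:
    """Cluster representatives plus their optimised voting fractions."""

    exemplar_indices: np.ndarray
    fractions: np.ndarray
    models: list[MulticlassModel]
    classes: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.fractions < 0) or np.any(self.fractions > 1):
            raise ValueError("fractions must lie in [0, 1]")


def build_model_pool(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    grid: GridSpec | None = None,
    eval_indices: np.ndarray | None = None,
    train_indices: np.ndarray | None = None,
    resubstitution: bool = False,
) -> ModelPool:
    """Train every grid member and cache its evaluation-split behaviour.

    ``eval_indices`` rows are held out of training and used to compute
    pool predictions and misclassification indicators; the remaining
    rows train every member.  With ``resubstitution=True`` the
    indicators are instead computed on the training rows themselves
    (the held-out variant is the default).  Training and evaluation
    index sets must be disjoint.
    """
    grid = GridSpec() if grid is None else grid
    if len(grid) == 0:
        raise ValueError("empty grid")
    if isinstance(features, FeatureMatrix):
        x = features.values
        if labels is None:
            labels = features.labels
    else:
        x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n = x.shape[0]
    if eval_indices is None and not resubstitution:
        raise ValueError("eval_indices required unless resubstitution=True")
    if resubstitution:
        train_idx = np.arange(n) if train_indices is None else np.asarray(train_indices)
        eval_idx = train_idx
    else:
        eval_idx = np.asarray(eval_indices)
        if train_indices is None:
            train_idx = np.setdiff1d(np.arange(n), eval_idx)
        else:
            train_idx = np.asarray(train_indices)
            if np.intersect1d(train_idx, eval_idx).size:
                raise ValueError("eval split overlaps training rows")

    xt, yt = x[train_idx], y[train_idx]
    xe, ye = x[eval_idx], y[eval_idx]
    members: list[MulticlassModel] = []
    preds = np.empty((len(grid), len(ye)), dtype=int)
    for i, (scheme, lc, ls) in enumerate(grid.combinations()):
        spec = BinaryLearnerSpec(penalty_C=10.0**lc, kernel_scale_sigma=10.0**ls)
        model = train_multiclass(xt, yt, scheme=scheme, spec=spec)
        members.append(model)
        preds[i] = model.predict_labels(xe)
    indicators = (preds != ye[None, :]).astype(float)
    return ModelPool(members=members, coords=grid.combinations(),
                     pool_predictions=preds, truth=np.asarray(ye),
                     indicators=indicators, classes=members[0].classes)


def classifier_distance_matrix(pool: ModelPool | np.ndarray) -> np.ndarray:
    """Pairwise classifier distance from misclassification indicators.

    Accepts a :class:`ModelPool` or a raw members × m 0/1 indicator
    matrix.  Entry (i, j) is 1 − (1/2m) Σ_k (d_ik Δ d_jk); with 0/1
    indicators this is 1 minus the fraction of evaluation samples both
    members mislabel.  Symmetric, entries in [0, 1], and the diagonal
    equals 1 minus each member's error rate.
    """
    b = pool.indicators if isinstance(pool, ModelPool) else np.asarray(pool, dtype=float)
    if b.ndim != 2:
        raise ValueError("indicator matrix must be 2-D")
    m = b.shape[1]
    if m == 0:
        raise ValueError("no evaluation samples (m = 0)")
    joint = b @ b.T  # counts of samples both members get wrong
    return 1.0 - joint / m


def _ap_exemplars(similarity: np.ndarray, preference: float) -> tuple[np.ndarray, bool]:
    """Run affinity propagation; returns (exemplar indices, converged)."""
    from sklearn.exceptions import ConvergenceWarning

    ap = AffinityPropagation(affinity="precomputed", damping=0.9, max_iter=500,
                             convergence_iter=50, preference=preference,
                             random_state=0)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        ap.fit(similarity)
    converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    centers = ap.cluster_centers_indices_
    if centers is None or len(centers) == 0:
        return np.array([], dtype=int), False
    return np.asarray(centers, dtype=int), converged


def cluster_pool(
    dist: np.ndarray,
    target_clusters: int = 7,
    max_bisect: int = 30,
    n_scan: int = 24,
) -> np.ndarray:
    """Affinity-propagation exemplars at (or nearest to) a target count.

    Affinity propagation does not take a cluster count, so the shared
    preference is tuned on s(i, j) = −dist(i, j): a ladder of candidate
    preferences spanning the similarity range is scanned to bracket the
    target exemplar count (non-converged runs are discarded), then the
    bracket is bisected.  If the exact count is unreachable — e.g. a
    degenerate pool of near-identical members — the closest achieved
    count is returned with a :class:`ClusterCountWarning`.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    if target_clusters < 1 or target_clusters > n:
        raise ValueError("target_clusters must be in [1, n]")
    s = -d

    smin, smax = float(s.min()), float(s.max())
    span = max(smax - smin, 1e-6)
    best: tuple[np.ndarray, int] | None = None  # (exemplars, count)

    def probe(p: float) -> int | None:
        """Exemplar count at preference p, or None if AP did not converge."""
        nonlocal best
        ex, ok = _ap_exemplars(s, p)
        if not ok:
            return None
        cnt = len(ex)
        if best is None or abs(cnt - target_clusters) < abs(best[1] - target_clusters):
            best = (ex, cnt)
        return cnt

    # coarse scan from "everything one cluster" to "everything its own";
    # the geometric tail reaches the deep-preference single-cluster regime
    ladder = np.concatenate([
        smin - span * np.array([300.0, 100.0, 30.0, 10.0, 5.0]),
        np.linspace(smin - 2.0 * span, smax, n_scan),
    ])
    profile: list[tuple[float, int]] = []
    for p in ladder:
        cnt = probe(p)
        if cnt is None:
            continue
        if cnt == target_clusters:
            return np.sort(best[0])
        profile.append((p, cnt))

    # tightest bracket: adjacent scanned preferences straddling the target
    # (exemplar counts are only roughly monotone in the preference, so the
    # bracket with the smallest overshoot is the most informative)
    bracket = None
    for (p1, c1), (p2, c2) in zip(profile, profile[1:]):
        if c1 < target_clusters <= c2:
            if bracket is None or c2 < bracket[3]:
                bracket = (p1, p2, c1, c2)
    if bracket is not None:
        lo, hi = bracket[0], bracket[1]
        for _ in range(max_bisect):
            mid = 0.5 * (lo + hi)
            cnt = probe(mid)
            if cnt == target_clusters:
                return np.sort(best[0])
            if cnt is None:
                # nudge the non-converged midpoint away deterministically
                lo = lo + 0.25 * (mid - lo)
                continue
            if cnt < target_clusters:
                lo = mid
            else:
                hi = mid

    achieved = 0 if best is None else best[1]
    warnings.warn(
        f"preference search reached {achieved} exemplars instead of "
        f"{target_clusters}", ClusterCountWarning)
    if best is None:
        # nothing converged: fall back to the single most central member
        return np.array([int(np.argmin(d.sum(axis=1)))])
    return np.sort(best[0])


def cluster_representatives(
    dist: np.ndarray,
    pool: ModelPool,
    target_clusters: int = 7,
    representative: str = "exemplar",
) -> np.ndarray:
    """Exemplar indices, optionally swapped for each cluster's most
    accurate member (``representative='best'``)."""
    exemplars = cluster_pool(dist, target_clusters)
    if representative == "exemplar":
        return exemplars
    if representative != "best":
        raise ValueError("representative must be 'exemplar' or 'best'")
    # assign every member to the nearest exemplar, then pick the most
    # accurate member inside each cluster (ties -> lowest index)
    acc = pool.member_accuracies()
    assign = np.argmin(dist[:, exemplars], axis=1)
    reps = []
    for ci in range(len(exemplars)):
        members = np.flatnonzero(assign == ci)
        reps.append(members[np.argmax(acc[members])])
    return np.sort(np.asarray(reps, dtype=int))


FRACTION_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))


def _combined_accuracy(p_list, fractions, y, classes) -> float:
    y_mat = sum(f * p for f, p in zip(fractions, p_list)) / len(p_list)
    pred = classes[np.argmax(y_mat, axis=1)]
    return float(np.mean(pred == y))


def optimize_fractions(
    models: list[MulticlassModel],
    val_features: FeatureMatrix | np.ndarray,
    val_labels: np.ndarray | None = None,
    max_sweeps: int = 20,
) -> np.ndarray:
    """Coordinate-ascent search of voting fractions on validation data.

    Fractions start at 1.0 and are swept in member order over the grid
    {0.0, 0.1, …, 1.0}, each move kept only if it strictly improves
    combined validation accuracy (ties keep the incumbent value); the
    sweep repeats until a full pass changes nothing.  Deterministic
    given its inputs.
    """
    if isinstance(val_features, FeatureMatrix):
        if val_labels is None:
            val_labels = val_features.labels
    yv = np.asarray(val_labels)
    if yv.size == 0:
        raise ValueError("empty validation set")
    classes = models[0].classes
    p_list = [m.predict_scores(val_features) for m in models]
    fractions = np.ones(len(models))
    for _ in range(max_sweeps):
        changed = False
        for i in range(len(models)):
            best_f = fractions[i]
            best_acc = _combined_accuracy(p_list, fractions, yv, classes)
            for f in FRACTION_GRID:
                if f == fractions[i]:
                    continue
                trial = fractions.copy()
                trial[i] = f
                acc = _combined_accuracy(p_list, trial, yv, classes)
                if acc > best_acc:
                    best_acc, best_f = acc, f
            if best_f != fractions[i]:
                fractions[i] = best_f
                changed = True
        if not changed:
            break
    return fractions


def build_ensemble(
    pool: ModelPool,
    val_features: FeatureMatrix | np.ndarray,
    val_labels: np.ndarray | None = None,
    target_clusters: int = 7,
    representative: str = "exemplar",
) -> EnsembleModel:
    """Distance → clustering → fraction optimisation, end to end."""
    dist = classifier_distance_matrix(pool)
    reps = cluster_representatives(dist, pool, target_clusters, representative)
    models = [pool.members[i] for i in reps]
    fractions = optimize_fractions(models, val_features, val_labels)
    return EnsembleModel(exemplar_indices=reps, fractions=fractions,
                         models=models, classes=pool.classes)


def ensemble_predict(
    ensemble: EnsembleModel,
    features: FeatureMatrix | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Fractional-vote score matrix and predicted labels.

    Y = (1/n) Σ_i F_i P_i over the n ensemble members; the label is the
    row argmax (lowest class index on ties).
    """
    p_list = [m.predict_scores(features) for m in ensemble.models]
    y_mat = sum(f * p for f, p in zip(ensemble.fractions, p_list)) / len(p_list)
    labels = ensemble.classes[np.argmax(y_mat, axis=1)]
    return y_mat, labels


def row_normalize(y_mat: np.ndarray) -> np.ndarray:
    """Row-normalised copy of an ensemble score matrix (zero rows kept)."""
    s = y_mat.sum(axis=1, keepdims=True)
    s[s == 0] = 1.0
    return y_mat / s
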