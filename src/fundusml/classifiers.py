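"""Multiclass decision schemes over binary RBF-kernel SVM base learners.

Three decompositions of a K-class problem into binary large-margin
problems are provided:

* **OVO** (one-vs-one): K(K−1)/2 pairwise learners; predicted class is
  the one collecting most pairwise votes.
* **OVA** (one-vs-all): one learner per class against the rest;
  predicted class has the largest decision value.
* **DAG** (directed acyclic graph): the same K(K−1)/2 pairwise learners
  as OVO, evaluated as a decision list — keep an ordered active-class
  list, test the (first, last) pair, eliminate the loser; K−1 binary
  tests classify a sample.

The base learner is pluggable; by default it is a soft-margin RBF SVM
(scikit-learn ``SVC``) with kernel k(x, y) = exp(−‖x−y‖² / (2σ²)), i.e.
``gamma = 1/(2σ²)`` with σ the kernel scaling factor.  Defaults C=100,
σ=10.  The decision schemes, score calibration and tie handling are the
substance of this module, not the quadratic-program solver.

Per-feature standardisation (centre/scale fitted on the training rows)
is applied inside the model so RBF distances are comparable across
heterogeneous descriptor blocks.  Ties are broken toward the lowest
class index everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from fundusml.datatypes import FeatureMatrix

SCHEMES = ("OVO", "OVA", "DAG", "pluggable")


class FeatureDimensionError(ValueError):
    """Prediction-time feature dimension differs from training dimension."""


@dataclass(frozen=True)
class BinaryLearnerSpec:
    """RBF binary learner hyper-parameters: penalty C and kernel scale σ."""

    penalty_C: float = 100.0
    kernel_scale_sigma: float = 10.0

    def __post_init__(self) -> None:
        if self.penalty_C <= 0 or self.kernel_scale_sigma <= 0:
            raise ValueError("penalty_C and kernel_scale_sigma must be > 0")

    @property
    def gamma(self) -> float:
        return 1.0 / (2.0 * self.kernel_scale_sigma**2)


def _default_binary_factory(spec: BinaryLearnerSpec):
    return SVC(kernel="rbf", C=spec.penalty_C, gamma=spec.gamma)


def make_random_forest_baseline(n_estimators: int = 1000, max_features: int = 5,
                                random_state: int = 0) -> RandomForestClassifier:
    """Random-forest baseline: 1000 trees, five predictors per node."""
    return RandomForestClassifier(n_estimators=n_estimators,
                                  max_features=max_features,
                                  random_state=random_state)


def make_ann_baseline(hidden: tuple[int, int] = (64, 64), random_state: int = 0) -> MLPClassifier:
    """Two-hidden-layer feed-forward ANN baseline."""
    return MLPClassifier(hidden_layer_sizes=hidden, max_iter=500,
                         random_state=random_state)


@dataclass
class MulticlassModel:
    """A trained multiclass decision scheme.

    ``submodels`` is keyed by class pair ``(a, b)`` with ``a < b`` for
    OVO/DAG (positive decision value votes for ``a``) or by class index
    for OVA (positive decision value votes for that class).  For
    ``pluggable`` the wrapped estimator handles multiclass natively.
    """

    scheme: str
    classes: np.ndarray
    submodels: dict = field(default_factory=dict)
    mean_: np.ndarray | None = None
    scale_: np.ndarray | None = None
    estimator: Any = None
    n_features_: int = 0
    #: decision-list node evaluations per sample in the last DAG predict
    last_dag_evals_per_sample: np.ndarray | None = None

    # -- helpers ----------------------------------------------------------
    def _prep(self, features) -> np.ndarray:
        x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.n_features_:
            raise FeatureDimensionError(
                f"expected {self.n_features_} features, got {x.shape[1]}"
            )
        if self.mean_ is not None:
            x = (x - self.mean_) / self.scale_
        return x

    def _pair_decisions(self, x: np.ndarray) -> dict[tuple[int, int], np.ndarray]:
        return {pair: m.decision_function(x) for pair, m in self.submodels.items()}

    def _ovo_votes(self, x: np.ndarray) -> np.ndarray:
        k = len(self.classes)
        votes = np.zeros((x.shape[0], k))
        for (a, b), m in self.submodels.items():
            d = m.decision_function(x)
            votes[:, a] += (d >= 0)
            votes[:, b] += (d < 0)
        return votes

    def _ova_decisions(self, x: np.ndarray) -> np.ndarray:
        k = len(self.classes)
        if k == 2 and len(self.submodels) == 1:
            d = self.submodels[0].decision_function(x)
            return np.column_stack([d, -d])
        return np.column_stack([self.submodels[c].decision_function(x) for c in range(k)])

    def _dag_eliminate(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Run the decision list; returns (winner index, elimination step per class).

        ``elim_step[i, c]`` is the step (1-based) at which class c was
        eliminated for sample i; the winner keeps step K.
        """
        n, k = x.shape[0], len(self.classes)
        cache: dict[tuple[int, int], np.ndarray] = {}

        def dec(pair):
            if pair not in cache:
                cache[pair] = self.submodels[pair].decision_function(x)
            return cache[pair]

        winner = np.empty(n, dtype=int)
        elim_step = np.full((n, k), k, dtype=int)
        evals = np.zeros(n, dtype=int)
        for i in range(n):
            active = list(range(k))
            step = 1
            while len(active) > 1:
                a, b = active[0], active[-1]
                d = dec((a, b))[i]
                evals[i] += 1
                loser = b if d >= 0 else a
                active.remove(loser)
                elim_step[i, loser] = step
                step += 1
            winner[i] = active[0]
        self.last_dag_evals_per_sample = evals
        return winner, elim_step

    # -- public API -------------------------------------------------------
    def predict_labels(self, features) -> np.ndarray:
        x = self._prep(features)
        if self.scheme == "pluggable":
            idx = np.searchsorted(self.classes, self.estimator.predict(
                features.values if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)))
            return self.classes[idx]
        if self.scheme == "OVO":
            return self.classes[np.argmax(self._ovo_votes(x), axis=1)]
        if self.scheme == "OVA":
            return self.classes[np.argmax(self._ova_decisions(x), axis=1)]
        if self.scheme == "DAG":
            winner, _ = self._dag_eliminate(x)
            return self.classes[winner]
        raise ValueError(f"unknown scheme {self.scheme!r}")

    def predict_scores(self, features) -> np.ndarray:
        """n×K non-negative score matrix with unit row sums.

        OVO: pairwise-vote fractions.  OVA: softmax over decision
        values.  DAG: elimination-order weights (class removed at step t
        scores t, the winner scores K, normalised) so the score argmax
        always matches the decision-list label.  Pluggable estimators
        use ``predict_proba`` when available.
        """
        x = self._prep(features)
        k = len(self.classes)
        if self.scheme == "pluggable":
            raw = (features.values if isinstance(features, FeatureMatrix)
                   else np.asarray(features, dtype=float))
            if hasattr(self.estimator, "predict_proba"):
                p = self.estimator.predict_proba(raw)
            else:
                pred = self.estimator.predict(raw)
                p = np.zeros((raw.shape[0], k))
                p[np.arange(raw.shape[0]), np.searchsorted(self.classes, pred)] = 1.0
            return p
        if self.scheme == "OVO":
            votes = self._ovo_votes(x)
            total = k * (k - 1) / 2
            return votes / total
        if self.scheme == "OVA":
            d = self._ova_decisions(x)
            d = d - d.max(axis=1, keepdims=True)
            e = np.exp(d)
            return e / e.sum(axis=1, keepdims=True)
        if self.scheme == "DAG":
            _, elim = self._dag_eliminate(x)
            w = elim.astype(float)
            return w / w.sum(axis=1, keepdims=True)
        raise ValueError(f"unknown scheme {self.scheme!r}")


def train_multiclass(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    scheme: str = "OVO",
    spec: BinaryLearnerSpec | None = None,
    binary_factory: Callable[[BinaryLearnerSpec], Any] | None = None,
    estimator: Any = None,
    classes: np.ndarray | None = None,
) -> MulticlassModel:
    """Fit a multiclass decision scheme on labelled feature rows.

    ``classes`` defaults to the sorted distinct labels present; naming a
    class with no training sample is rejected.  For ``scheme='pluggable'``
    pass a fitted-API estimator (e.g. a random forest) via ``estimator``.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    if isinstance(features, FeatureMatrix):
        x = features.values
        if labels is None:
            labels = features.labels
    else:
        x = np.asarray(features, dtype=float)
    if labels is None:
        raise ValueError("labels are required")
    y = np.asarray(labels)
    present = np.unique(y)
    if classes is None:
        classes = present
    else:
        classes = np.asarray(classes)
        missing = [c for c in classes if c not in set(present.tolist())]
        if missing:
            raise ValueError(f"classes absent from labels: {missing}")
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")

    spec = spec or BinaryLearnerSpec()
    factory = binary_factory or _default_binary_factory

    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale = np.where(scale < 1e-12, 1.0, scale)
    model = MulticlassModel(scheme=scheme, classes=classes, mean_=mean,
                            scale_=scale, n_features_=x.shape[1])
    if scheme == "pluggable":
        if estimator is None:
            raise ValueError("scheme='pluggable' requires an estimator")
        estimator.fit(x, y)
        model.estimator = estimator
        model.mean_ = None  # estimator consumes raw features
        model.scale_ = None
        return model

    xs = (x - mean) / scale
    k = len(classes)
    idx_of = {c: i for i, c in enumerate(classes.tolist())}
    yi = np.array([idx_of[v] for v in y.tolist()])

    if scheme in ("OVO", "DAG") or k == 2:
        # pairwise learners; for K=2 all three schemes share this single model
        for a in range(k):
            for b in range(a + 1, k):
                m = (yi == a) | (yi == b)
                yb = np.where(yi[m] == a, 1, -1)
                clf = factory(spec)
                clf.fit(xs[m], yb)
                if scheme == "OVA":
                    model.submodels[a] = clf  # K=2 OVA mirror
                else:
                    model.submodels[(a, b)] = clf
        return model

    # OVA, K > 2: one learner per class against the rest
    for a in range(k):
        yb = np.where(yi == a, 1, -1)
        clf = factory(spec)
        clf.fit(xs, yb)
        model.submodels[a] = clf
    return model
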