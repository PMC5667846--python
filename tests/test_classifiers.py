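"""OVO / OVA / DAG decision schemes over binary RBF learners."""

import numpy as np
import pytest

from fundusml.classifiers import (
    BinaryLearnerSpec,
    FeatureDimensionError,
    MulticlassModel,
    make_random_forest_baseline,
    train_multiclass,
)
from fundusml.synthetic import generate_feature_dataset


class _Const:
    """Stub binary learner with a fixed decision value."""

    def __init__(self, d):
        self.d = d

    def decision_function(self, x):
        return np.full(x.shape[0], self.d)


def _stub_model(scheme, submodels, k=3, d=2):
    return MulticlassModel(scheme=scheme, classes=np.arange(k),
                           submodels=submodels, mean_=np.zeros(d),
                           scale_=np.ones(d), n_features_=d)


class TestTraining:
    def test_submodel_counts(self, separable_features):
        fm = separable_features
        assert len(train_multiclass(fm, scheme="OVO").submodels) == 3
        assert len(train_multiclass(fm, scheme="OVA").submodels) == 3
        assert len(train_multiclass(fm, scheme="DAG").submodels) == 3

    def test_ten_class_ovo_has_45_submodels(self):
        fm = generate_feature_dataset(10, 6, dim=8, separation=5.0, seed=1)
        m = train_multiclass(fm, scheme="OVO")
        assert len(m.submodels) == 10 * 9 // 2

    def test_binary_collapse_single_submodel_and_agreement(self):
        fm = generate_feature_dataset(2, 20, dim=8, separation=3.0, seed=2)
        preds = {}
        for scheme in ("OVO", "OVA", "DAG"):
            m = train_multiclass(fm, scheme=scheme)
            assert len(m.submodels) == 1
            preds[scheme] = m.predict_labels(fm)
        assert np.array_equal(preds["OVO"], preds["OVA"])
        assert np.array_equal(preds["OVO"], preds["DAG"])

    def test_separable_classes_reach_perfect_training_accuracy(self, separable_features):
        fm = separable_features
        for scheme in ("OVO", "OVA", "DAG"):
            m = train_multiclass(fm, scheme=scheme)
            assert np.mean(m.predict_labels(fm) == fm.labels) == 1.0

    def test_absent_class_rejected_by_name(self, separable_features):
        with pytest.raises(ValueError, match="7"):
            train_multiclass(separable_features, classes=np.array([0, 1, 2, 7]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_multiclass(np.zeros((4, 2)), np.zeros(4, dtype=int))

    def test_permutation_invariant_predictions(self, separable_features):
        fm = separable_features
        m1 = train_multiclass(fm.values, fm.labels, scheme="OVO")
        perm = np.random.default_rng(0).permutation(len(fm.labels))
        m2 = train_multiclass(fm.values[perm], fm.labels[perm], scheme="OVO")
        probe = generate_feature_dataset(n_classes=3, n_per_class=10, dim=16,
                                         separation=10.0, seed=99).values
        assert np.array_equal(m1.predict_labels(probe), m2.predict_labels(probe))


class TestDecision:
    def test_ovo_strict_majority(self):
        m = _stub_model("OVO", {(0, 1): _Const(1), (0, 2): _Const(1),
                                (1, 2): _Const(1)})  # votes (2, 1, 0)
        assert m.predict_labels(np.zeros((1, 2)))[0] == 0

    def test_ovo_three_way_tie_returns_lowest_index(self):
        m = _stub_model("OVO", {(0, 1): _Const(-1), (0, 2): _Const(1),
                                (1, 2): _Const(-1)})  # votes (1, 1, 1)
        assert m.predict_labels(np.zeros((1, 2)))[0] == 0
        assert np.allclose(m.predict_scores(np.zeros((1, 2))), 1 / 3)

    def test_dag_eliminates_k_minus_1_times(self):
        fm = generate_feature_dataset(4, 10, dim=8, separation=5.0, seed=3)
        m = train_multiclass(fm, scheme="DAG")
        m.predict_labels(fm)
        assert np.all(m.last_dag_evals_per_sample == 3)

    def test_dimension_mismatch_rejected(self, separable_features):
        m = train_multiclass(separable_features, scheme="OVO")
        with pytest.raises(FeatureDimensionError):
            m.predict_labels(np.zeros((2, 5)))


class TestScores:
    def test_binary_ovo_vote_is_one_hot(self):
        m = _stub_model("OVO", {(0, 1): _Const(-1)}, k=2)
        assert np.allclose(m.predict_scores(np.zeros((1, 2))), [[0, 1]])

    def test_rows_sum_to_one(self, separable_features):
        fm = separable_features
        for scheme in ("OVO", "OVA", "DAG"):
            m = train_multiclass(fm, scheme=scheme)
            p = m.predict_scores(fm)
            assert p.min() >= 0
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_ova_equal_decisions_give_uniform_softmax(self):
        m = _stub_model("OVA", {0: _Const(0), 1: _Const(0), 2: _Const(0)})
        assert np.allclose(m.predict_scores(np.zeros((1, 2))), 1 / 3)

    def test_argmax_of_scores_matches_labels(self, moderate_features):
        fm = moderate_features
        probe = np.random.default_rng(4).normal(size=(40, fm.feature_dim))
        for scheme in ("OVO", "OVA", "DAG"):
            m = train_multiclass(fm, scheme=scheme)
            lab = m.predict_labels(probe)
            sc = m.predict_scores(probe)
            assert np.array_equal(m.classes[np.argmax(sc, axis=1)], lab)


def test_rbf_parameterization_uses_sigma_as_scale():
    spec = BinaryLearnerSpec(penalty_C=100.0, kernel_scale_sigma=10.0)
    assert spec.gamma == pytest.approx(1.0 / 200.0)
    with pytest.raises(ValueError):
        BinaryLearnerSpec(penalty_C=-1.0)


def test_pluggable_random_forest_slot(separable_features):
    fm = separable_features
    m = train_multiclass(fm, scheme="pluggable",
                         estimator=make_random_forest_baseline(n_estimators=20))
    assert np.mean(m.predict_labels(fm) == fm.labels) == 1.0
    p = m.predict_scores(fm)
    assert np.allclose(p.sum(axis=1), 1.0)
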