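"""Confusion-matrix metrics and ROC analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import cohen_kappa_score, mutual_info_score, roc_auc_score

from fundusml.metrics import (
    ConfusionMatrix,
    accuracy,
    confusion,
    kappa,
    rci,
    rci_unnormalized,
    roc_auc_youden,
)

Q_45_5 = np.array([[45.0, 5.0], [5.0, 45.0]])


class TestConfusion:
    def test_diagonal_hand_count(self):
        cm = confusion([0, 1], [0, 1], 2)
        assert np.array_equal(cm.q, np.eye(2))

    def test_off_diagonal_hand_count(self):
        cm = confusion([0, 0, 1], [1, 1, 1], 2)
        assert np.array_equal(cm.q, [[0, 2], [0, 1]])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion([], [], 2)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 3], [0, 1], 2)


class TestClosedForms:
    def test_balanced_binary_matrix(self):
        assert accuracy(Q_45_5) == pytest.approx(0.9)
        assert kappa(Q_45_5) == pytest.approx(0.8)
        # (ln 2 - H_b(0.1)) / ln 2
        hb = -(0.9 * np.log(0.9) + 0.1 * np.log(0.1))
        assert rci(Q_45_5) == pytest.approx((np.log(2) - hb) / np.log(2))
        assert rci(Q_45_5) == pytest.approx(0.531, abs=5e-4)

    def test_perfect_diagonal(self):
        q = np.diag([3.0, 7.0, 2.0])
        assert accuracy(q) == 1.0
        assert rci(q) == pytest.approx(1.0)
        assert kappa(q) == pytest.approx(1.0)

    def test_all_mass_off_diagonal(self):
        q = np.array([[0.0, 5.0], [5.0, 0.0]])
        assert accuracy(q) == 0.0

    def test_constant_predictor_has_zero_rci(self):
        q = np.array([[30.0, 0.0], [70.0, 0.0]])
        assert rci(q) == pytest.approx(0.0)

    def test_independence_matrix_has_zero_kappa(self):
        q = np.outer([0.3, 0.7], [0.6, 0.4]) * 100
        assert kappa(q) == pytest.approx(0.0)

    def test_degenerate_margins_warn_and_return_zero(self):
        with pytest.warns(UserWarning):
            assert kappa(np.array([[5.0]])) == 0.0

    def test_kappa_equals_2acc_minus_1_on_balanced_symmetric_2x2(self):
        for a in (0.6, 0.75, 0.874, 0.95):
            q = np.array([[a / 2, (1 - a) / 2], [(1 - a) / 2, a / 2]]) * 200
            assert kappa(q) == pytest.approx(2 * a - 1)


class TestOracles:
    def test_rci_is_normalized_mutual_information(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = rng.integers(0, 4, 100)
            p = rng.integers(0, 4, 100)
            cm = confusion(t, p, 4)
            mi = mutual_info_score(t, p)
            assert rci_unnormalized(cm) == pytest.approx(mi, abs=1e-10)
            h = mutual_info_score(t, t)
            assert rci(cm) == pytest.approx(mi / h, abs=1e-10)

    def test_kappa_matches_sklearn(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            t = rng.integers(0, 5, 150)
            p = rng.integers(0, 5, 150)
            cm = confusion(t, p, 5)
            assert kappa(cm) == pytest.approx(cohen_kappa_score(t, p), abs=1e-10)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_rci_kappa_invariant_under_class_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        q = rng.integers(0, 20, (4, 4)).astype(float)
        if q.sum() == 0:
            q[0, 0] = 1
        perm = rng.permutation(4)
        qp = q[np.ix_(perm, perm)]
        assert rci(q) == pytest.approx(rci(qp), abs=1e-10)
        assert kappa(q) == pytest.approx(kappa(qp), abs=1e-10)


class TestRoc:
    def test_perfectly_separated_scores(self):
        r = roc_auc_youden([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert r.auc == pytest.approx(1.0)
        assert r.youden_index == pytest.approx(1.0)

    def test_identical_scores_are_uninformative(self):
        r = roc_auc_youden([0.5] * 10, [0] * 5 + [1] * 5)
        assert r.auc == pytest.approx(0.5)

    def test_pair_counting_example(self):
        r = roc_auc_youden([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert r.auc == pytest.approx(0.75)

    def test_trapezoid_equals_concordant_pair_fraction(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = 30
            s = rng.permutation(n) / n  # tie-free scores
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            r = roc_auc_youden(s, y)
            pos, neg = s[y == 1], s[y == 0]
            conc = np.mean(pos[:, None] > neg[None, :])
            assert r.auc == pytest.approx(conc, abs=1e-12)

    def test_matches_sklearn_auc_with_ties(self):
        rng = np.random.default_rng(3)
        s = rng.integers(0, 5, 60) / 4.0  # heavy ties
        y = rng.integers(0, 2, 60)
        assert roc_auc_youden(s, y).auc == pytest.approx(roc_auc_score(y, s))

    def test_youden_cutoff_prefers_lowest_threshold_on_ties(self):
        # thresholds 0.4 and 0.2 both reach J = 0.5 here
        r = roc_auc_youden([0.1, 0.2, 0.3, 0.4], [0, 1, 0, 1])
        assert r.youden_index == pytest.approx(0.5)
        assert r.youden_cutoff == pytest.approx(0.2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc_youden([0.1, 0.9], [1, 1])


def test_negative_entries_rejected():
    with pytest.raises(ValueError):
        ConfusionMatrix(q=np.array([[1.0, -1.0], [0.0, 1.0]]))
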