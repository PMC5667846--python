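"""Model pool, classifier distance, clustering, and fractional voting."""

import numpy as np
import pytest

from fundusml.ensemble import (
    ClusterCountWarning,
    EnsembleModel,
    GridSpec,
    build_ensemble,
    build_model_pool,
    classifier_distance_matrix,
    cluster_pool,
    ensemble_predict,
    optimize_fractions,
    row_normalize,
)
from fundusml.synthetic import generate_feature_dataset


def small_pool(grid=None, seed=0):
    fm = generate_feature_dataset(3, 20, dim=8, separation=1.5, seed=seed)
    ev = np.arange(0, 60, 3)  # every third row held out
    grid = grid or GridSpec(schemes=("OVO",), logC_values=(0, 2),
                            logSigma_values=(0, 1))
    return build_model_pool(fm.values, fm.labels, grid=grid, eval_indices=ev), fm


class TestGridAndPool:
    def test_default_grid_is_300_combinations(self):
        grid = GridSpec()
        assert len(grid) == 300
        combos = grid.combinations()
        assert len(set(combos)) == 300
        # 10 integer log-values per axis, each in (-5, 5]
        assert len(grid.logC_values) == 10
        assert all(-5 < v <= 5 for v in grid.logC_values)

    def test_pool_size_matches_grid_product(self):
        pool, _ = small_pool()
        assert len(pool.members) == 4
        assert pool.pool_predictions.shape == (4, 20)
        assert set(np.unique(pool.indicators)) <= {0.0, 1.0}

    def test_overlapping_eval_split_rejected(self):
        fm = generate_feature_dataset(2, 10, dim=4, separation=1.0, seed=1)
        with pytest.raises(ValueError, match="overlap"):
            build_model_pool(fm.values, fm.labels,
                             grid=GridSpec(schemes=("OVO",), logC_values=(0,),
                                           logSigma_values=(0,)),
                             eval_indices=np.arange(5),
                             train_indices=np.arange(3, 20))

    def test_empty_grid_rejected(self):
        fm = generate_feature_dataset(2, 10, dim=4, separation=1.0, seed=1)
        with pytest.raises(ValueError, match="empty"):
            build_model_pool(fm.values, fm.labels,
                             grid=GridSpec(schemes=(), logC_values=(),
                                           logSigma_values=()),
                             eval_indices=np.arange(5))


class TestDistance:
    def test_shared_errors_hand_case(self):
        """Two members wrong on the same 3 of 10 samples -> distance 0.7."""
        b = np.zeros((2, 10))
        b[0, :3] = 1
        b[1, :3] = 1
        d = classifier_distance_matrix(b)
        assert d[0, 1] == pytest.approx(0.7)

    def test_disjoint_errors_give_distance_one(self):
        b = np.zeros((2, 10))
        b[0, :3] = 1
        b[1, 5:8] = 1
        assert classifier_distance_matrix(b)[0, 1] == pytest.approx(1.0)

    def test_all_wrong_gives_distance_zero(self):
        b = np.ones((2, 6))
        assert classifier_distance_matrix(b)[0, 1] == pytest.approx(0.0)

    def test_diagonal_equals_one_minus_error_rate(self):
        pool, _ = small_pool()
        d = classifier_distance_matrix(pool)
        assert np.allclose(np.diag(d), pool.member_accuracies())

    def test_matches_bruteforce_on_random_indicators(self):
        """1 - (1/2m) sum of (d_ik + d_jk on joint errors), element by element."""
        rng = np.random.default_rng(5)
        for _ in range(200):
            b = rng.integers(0, 2, size=(5, 12)).astype(float)
            d = classifier_distance_matrix(b)
            m = b.shape[1]
            for i in range(5):
                for j in range(5):
                    acc = sum(b[i, k] + b[j, k]
                              for k in range(m) if b[i, k] == 1 and b[j, k] == 1)
                    assert d[i, j] == pytest.approx(1 - acc / (2 * m))

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(6)
        b = rng.integers(0, 2, size=(10, 30)).astype(float)
        d = classifier_distance_matrix(b)
        assert np.allclose(d, d.T)
        assert d.min() >= 0 and d.max() <= 1

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            classifier_distance_matrix(np.zeros((3, 0)))


def planted_block_distance(n_blocks=7, block=10, within=0.05, across=0.9, seed=0):
    n = n_blocks * block
    rng = np.random.default_rng(seed)
    d = np.full((n, n), across) + rng.uniform(-0.02, 0.02, (n, n))
    for b in range(n_blocks):
        s = slice(b * block, (b + 1) * block)
        d[s, s] = within + rng.uniform(0, 0.01, (block, block))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


class TestClustering:
    def test_recovers_seven_planted_blocks(self):
        d = planted_block_distance()
        ex = cluster_pool(d, target_clusters=7)
        assert len(ex) == 7
        blocks = sorted(e // 10 for e in ex)
        assert blocks == list(range(7))  # one exemplar per block

    def test_single_cluster_target(self):
        d = planted_block_distance(n_blocks=3)
        ex = cluster_pool(d, target_clusters=1)
        assert len(ex) == 1

    def test_degenerate_constant_matrix_converges_or_warns(self):
        d = np.full((12, 12), 0.5)
        np.fill_diagonal(d, 0.0)
        with pytest.warns(ClusterCountWarning):
            # 5 clusters of identical members is not a stable AP solution
            ex = cluster_pool(d, target_clusters=5, max_bisect=8)
        assert len(ex) >= 1

    def test_non_symmetric_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            cluster_pool(d, target_clusters=2)


class _FixedScores:
    """Stub member with a fixed class-score matrix."""

    def __init__(self, p, classes=None):
        self.p = np.asarray(p, dtype=float)
        self.classes = classes if classes is not None else np.arange(self.p.shape[1])

    def predict_scores(self, features):
        return self.p


class TestFractions:
    def test_single_member_returns_full_fraction(self):
        m = _FixedScores(np.eye(3))
        f = optimize_fractions([m], np.zeros((3, 2)), np.arange(3))
        assert np.array_equal(f, [1.0])

    def test_identical_members_keep_initial_fractions(self):
        p = np.eye(4)
        members = [_FixedScores(p) for _ in range(3)]
        f = optimize_fractions(members, np.zeros((4, 2)), np.arange(4))
        assert np.array_equal(f, [1.0, 1.0, 1.0])

    def test_perfect_member_dominates_noise(self):
        rng = np.random.default_rng(7)
        y = np.repeat(np.arange(4), 5)
        perfect = np.zeros((20, 4))
        perfect[np.arange(20), y] = 1.0
        members = [_FixedScores(perfect)]
        for _ in range(6):
            noise = rng.dirichlet(np.ones(4), size=20)
            members.append(_FixedScores(noise))
        f = optimize_fractions(members, np.zeros((20, 2)), y)
        assert f[0] > 0
        ens = EnsembleModel(exemplar_indices=np.arange(7), fractions=f,
                            models=members, classes=np.arange(4))
        _, lab = ensemble_predict(ens, np.zeros((20, 2)))
        assert np.mean(lab == y) == 1.0

    def test_empty_validation_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            optimize_fractions([_FixedScores(np.eye(2))], np.zeros((0, 2)),
                               np.array([], dtype=int))


class TestEnsemblePredict:
    def test_identical_members_average_to_common_scores(self):
        p = np.array([[0.2, 0.8], [0.6, 0.4]])
        members = [_FixedScores(p) for _ in range(3)]
        ens = EnsembleModel(np.arange(3), np.ones(3), members, np.arange(2))
        y_mat, lab = ensemble_predict(ens, np.zeros((2, 2)))
        assert np.allclose(y_mat, p)
        assert np.array_equal(lab, [1, 0])

    def test_single_active_fraction_reduces_to_that_member(self):
        p1 = np.array([[1.0, 0.0]])
        p2 = np.array([[0.0, 1.0]])
        ens = EnsembleModel(np.arange(2), np.array([1.0, 0.0]),
                            [_FixedScores(p1), _FixedScores(p2)], np.arange(2))
        _, lab = ensemble_predict(ens, np.zeros((1, 2)))
        assert lab[0] == 0

    def test_tied_votes_break_to_lowest_index(self):
        p1 = np.array([[1.0, 0.0]])
        p2 = np.array([[0.0, 1.0]])
        ens = EnsembleModel(np.arange(2), np.array([1.0, 1.0]),
                            [_FixedScores(p1), _FixedScores(p2)], np.arange(2))
        y_mat, lab = ensemble_predict(ens, np.zeros((1, 2)))
        assert y_mat[0, 0] == y_mat[0, 1]
        assert lab[0] == 0

    def test_row_normalized_view(self):
        y_mat = np.array([[0.2, 0.2], [0.0, 0.0]])
        norm = row_normalize(y_mat)
        assert np.allclose(norm[0], [0.5, 0.5])
        assert np.allclose(norm[1], [0.0, 0.0])


def test_end_to_end_determinism():
    def run():
        pool, fm = small_pool(seed=3)
        ens = build_ensemble(pool, fm.values[:15], fm.labels[:15],
                             target_clusters=3)
        _, lab = ensemble_predict(ens, fm.values)
        return lab, ens.exemplar_indices, ens.fractions

    a, b = run(), run()
    assert np.array_equal(a[0], b[0])
    assert np.array_equal(a[1], b[1])
    assert np.array_equal(a[2], b[2])
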