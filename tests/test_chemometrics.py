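import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flourms.chemometrics import (
    ChemometricsConfig,
    bootstrap_vip,
    classification_accuracy_pct,
    cross_validated_q2,
    pca,
    permutation_test,
    plsda_fit,
    pretreat,
    roc_auc,
    run_discrimination,
    vip,
)


def two_class_data(n_per_class=10, p=40, n_informative=8, shift=3.0, seed=0):
    """Separable synthetic matrix: informative columns shifted in class 1."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per_class, p))
    y = np.repeat([0.0, 1.0], n_per_class)
    X[y == 1, :n_informative] += shift
    return X, y


class TestPretreat:
    def test_constant_feature_dropped(self):
        X = np.abs(np.random.default_rng(0).normal(10, 2, size=(6, 5)))
        X[:, 2] = 7.0
        Xs, tf = pretreat(X)
        assert Xs.shape == (6, 4)
        assert list(tf.dropped) == [2]

    def test_columns_centred_and_scaled(self):
        X = np.abs(np.random.default_rng(1).normal(100, 30, size=(8, 6)))
        Xs, _ = pretreat(X)
        assert np.allclose(Xs.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(Xs.std(axis=0), 1, atol=1e-12)

    def test_stored_transform_reproduces_training_matrix(self):
        X = np.abs(np.random.default_rng(2).normal(50, 10, size=(7, 9)))
        Xs, tf = pretreat(X)
        assert np.allclose(tf.apply(X), Xs)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            pretreat(np.zeros((4, 4)))


class TestPca:
    def test_separated_classes_split_on_pc1(self):
        rng = np.random.default_rng(0)
        X = rng.lognormal(10, 0.2, size=(20, 30))
        X[10:, :10] *= 5.0  # strong multiplicative class effect
        y = np.repeat([0, 1], 10)
        Xs, _ = pretreat(X)
        res = pca(Xs, 2)
        m0, m1 = res.scores[y == 0, 0], res.scores[y == 1, 0]
        assert abs(m0.mean() - m1.mean()) > 2 * (m0.std() + m1.std())

    def test_explained_variance_bounded(self):
        X = np.random.default_rng(3).normal(size=(10, 20))
        res = pca(X, 5)
        assert np.all(np.diff(res.explained_variance_pct) <= 1e-12)
        assert res.explained_variance_pct.sum() <= 100.0 + 1e-9

    def test_loadings_orthonormal(self):
        X = np.random.default_rng(4).normal(size=(12, 8))
        res = pca(X, 3)
        assert np.allclose(res.loadings.T @ res.loadings, np.eye(3), atol=1e-10)

    def test_duplicated_samples_get_identical_scores(self):
        X = np.random.default_rng(5).normal(size=(6, 10))
        X2 = np.vstack([X, X[0]])
        res = pca(X2 - X2.mean(0), 2)
        assert np.allclose(res.scores[0], res.scores[-1])


class TestPlsda:
    def test_r2y_high_on_separable_data(self):
        X, y = two_class_data()
        Xs = (X - X.mean(0)) / X.std(0)
        assert plsda_fit(Xs, y, 2).r2y > 0.9

    def test_informative_feature_dominates_first_weights(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 10))
        y = np.repeat([0.0, 1.0], 10)
        X[:, 3] = y * 4 + rng.normal(0, 0.05, 20)
        Xs = (X - X.mean(0)) / X.std(0)
        m = plsda_fit(Xs, y, 2)
        assert np.argmax(np.abs(m.weights[:, 0])) == 3

    def test_single_class_rejected(self):
        X = np.random.default_rng(7).normal(size=(6, 4))
        with pytest.raises(ValueError):
            plsda_fit(X, np.ones(6), 2)

    def test_scores_orthogonal(self):
        X, y = two_class_data(seed=8)
        Xs = (X - X.mean(0)) / X.std(0)
        T = plsda_fit(Xs, y, 3).scores
        off = T.T @ T - np.diag(np.diag(T.T @ T))
        assert np.allclose(off, 0, atol=1e-8)

    def test_matches_sklearn_pls_predictions(self):
        # independent implementation cross-check
        from sklearn.cross_decomposition import PLSRegression

        X, y = two_class_data(seed=9)
        Xs = (X - X.mean(0)) / X.std(0)
        ours = plsda_fit(Xs, y, 2).predict(Xs)
        ref = PLSRegression(n_components=2, scale=False).fit(Xs, y).predict(Xs).ravel()
        assert np.allclose(ours, ref, atol=1e-8)


class TestVip:
    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_mean_squared_vip_is_one(self, seed):
        X, y = two_class_data(seed=seed, p=25)
        Xs = (X - X.mean(0)) / X.std(0)
        v = vip(plsda_fit(Xs, y, 2))
        assert np.mean(v ** 2) == pytest.approx(1.0, abs=1e-9)

    def test_single_feature_vip_is_one(self):
        rng = np.random.default_rng(10)
        y = np.repeat([0.0, 1.0], 8)
        X = (y * 2 + rng.normal(0, 0.3, 16)).reshape(-1, 1)
        v = vip(plsda_fit(X - X.mean(0), y, 1))
        assert v[0] == pytest.approx(1.0, abs=1e-12)

    def test_planted_feature_has_maximum_vip(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(20, 30))
        y = np.repeat([0.0, 1.0], 10)
        X[:, 17] += y * 5
        Xs = (X - X.mean(0)) / X.std(0)
        assert np.argmax(vip(plsda_fit(Xs, y, 2))) == 17


class TestResampling:
    def test_bootstrap_vip_deterministic_per_seed(self):
        X, y = two_class_data(seed=12)
        cfg = ChemometricsConfig(n_bootstrap=20, seed=5)
        a = bootstrap_vip(X, y, cfg)
        b = bootstrap_vip(X, y, cfg)
        assert np.array_equal(a, b)

    def test_planted_features_rank_above_noise(self):
        X, y = two_class_data(n_informative=5, shift=4.0, seed=13)
        cfg = ChemometricsConfig(n_bootstrap=50, seed=1)
        v = bootstrap_vip(X, y, cfg)
        assert v[:5].min() > np.percentile(v[5:], 95)

    def test_q2_high_on_separable_low_on_permuted(self):
        X, y = two_class_data(seed=14)
        cfg = ChemometricsConfig(seed=3)
        assert cross_validated_q2(X, y, cfg) > 0.5
        rng = np.random.default_rng(0)
        null_q2 = np.mean([cross_validated_q2(X, rng.permutation(y), cfg)
                           for _ in range(10)])
        assert null_q2 <= 0.0

    def test_q2_does_not_exceed_r2y(self):
        X, y = two_class_data(seed=15)
        Xs = (X - X.mean(0)) / X.std(0)
        cfg = ChemometricsConfig(seed=4)
        assert cross_validated_q2(Xs, y, cfg) <= plsda_fit(Xs, y, 2).r2y

    def test_permutation_validates_real_signal(self):
        X, y = two_class_data(seed=16)
        cfg = ChemometricsConfig(n_permutations=50, seed=6)
        r2y = plsda_fit(X, y, 2).r2y
        q2 = cross_validated_q2(X, y, cfg)
        r2s, q2s, valid = permutation_test(X, y, cfg, r2y, q2)
        assert valid
        assert len(r2s) == len(q2s) == 50

    def test_permutation_rejects_random_labels(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(20, 30))
        y = rng.permutation(np.repeat([0.0, 1.0], 10))
        cfg = ChemometricsConfig(n_permutations=50, seed=7)
        r2y = plsda_fit(X, y, 2).r2y
        q2 = cross_validated_q2(X, y, cfg)
        _, _, valid = permutation_test(X, y, cfg, r2y, q2)
        assert not valid

    def test_zero_permutations_rejected(self):
        X, y = two_class_data(seed=18)
        with pytest.raises(ValueError):
            permutation_test(X, y, ChemometricsConfig(n_permutations=0), 1.0, 1.0)


class TestRoc:
    def test_perfect_separation(self):
        y = np.repeat([0, 1], 5)
        assert roc_auc(np.concatenate([np.zeros(5), np.ones(5)]), y) == 1.0

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(19)
        scores = rng.normal(size=20)
        y = np.repeat([0, 1], 10)
        assert roc_auc(scores, y) == pytest.approx(1 - roc_auc(-scores, y))

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(20)
        aucs = [roc_auc(rng.normal(size=20), np.repeat([0, 1], 10)) for _ in range(50)]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(21)
        scores = rng.normal(size=30)
        scores[:10] = scores[10:20]  # force ties
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        assert roc_auc(scores, y) == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_accuracy_at_optimal_threshold(self):
        y = np.repeat([0, 1], 5)
        scores = np.array([0.1, 0.2, 0.3, 0.4, 0.45, 0.5, 0.6, 0.7, 0.8, 0.9])
        assert classification_accuracy_pct(scores, y) == 100.0


class TestFullReport:
    def test_deterministic_given_seed(self):
        X = np.abs(np.random.default_rng(22).lognormal(10, 1, size=(12, 30)))
        X[6:, :5] *= 3.0
        labels = ["A"] * 6 + ["B"] * 6
        cfg = ChemometricsConfig(n_bootstrap=10, n_permutations=10, cv_folds=3, seed=9)
        r1 = run_discrimination(X, labels, cfg)
        r2 = run_discrimination(X, labels, cfg)
        assert r1.to_dict() == r2.to_dict()

    def test_requires_two_classes(self):
        X = np.abs(np.random.default_rng(23).normal(10, 1, size=(6, 8)))
        with pytest.raises(ValueError):
            run_discrimination(X, ["A"] * 6)
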