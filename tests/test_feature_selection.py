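import numpy as np
import pandas as pd
import pytest

from halochrom.color import CHANNELS
from halochrom.feature_selection import pca_correlation, rank_features, relieff


def make_table(X):
    cols = list(CHANNELS)[: X.shape[1]]
    return pd.DataFrame(X, columns=cols)


def brute_force_relieff(X, labels, k):
    """Naive reference ReliefF: literal loops over the definition, every row
    sampled once. Independent of the package implementation.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n, p = X.shape
    rng_ = X.max(axis=0) - X.min(axis=0)
    classes, counts = np.unique(labels, return_counts=True)
    priors = dict(zip(classes, counts / n))

    def diff(f, i, j):
        return 0.0 if rng_[f] == 0 else abs(X[i, f] - X[j, f]) / rng_[f]

    def dist(i, j):
        return sum(diff(f, i, j) for f in range(p))

    W = np.zeros(p)
    for i in range(n):
        for cls in classes:
            idx = [j for j in range(n) if labels[j] == cls and j != i]
            idx.sort(key=lambda j: (dist(i, j), j))
            nearest = idx[:k]
            for f in range(p):
                contrib = sum(diff(f, i, j) for j in nearest) / (n * k)
                if cls == labels[i]:
                    W[f] -= contrib
                else:
                    W[f] += priors[cls] / (1.0 - priors[labels[i]]) * contrib
    return W


class TestPcaCorrelation:
    def test_eigenvalues_match_independent_svd_solver(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((500, 12)) @ rng.standard_normal((12, 12))
        table = make_table(X)
        result = pca_correlation(table)
        from sklearn.decomposition import PCA  # independent oracle (SVD path)

        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        oracle = PCA(n_components=12).fit(Z)
        np.testing.assert_allclose(
            result.eigenvalues, oracle.explained_variance_, atol=1e-8
        )
        assert result.retained == int(np.sum(oracle.explained_variance_ > 1.0))

    def test_independent_noise_features_match_eigen_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((5000, 12))
        result = pca_correlation(make_table(X))
        oracle_vals = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
        np.testing.assert_allclose(result.eigenvalues, oracle_vals, atol=1e-10)
        assert result.retained == int(np.sum(oracle_vals > 1.0))

    def test_orthogonalized_features_retain_zero_components(self):
        # Exactly identity correlation: all eigenvalues 1, strict > 1 keeps none.
        rng = np.random.default_rng(2)
        X = rng.standard_normal((100, 6))
        Q, _ = np.linalg.qr(X - X.mean(axis=0))
        result = pca_correlation(make_table(Q))
        np.testing.assert_allclose(result.eigenvalues, 1.0, atol=1e-10)
        assert result.retained == 0

    def test_three_latent_factors_retain_three_components(self):
        rng = np.random.default_rng(3)
        factors = rng.standard_normal((2000, 3))
        loadings = np.zeros((3, 12))
        for f in range(3):
            loadings[f, 4 * f : 4 * f + 4] = 1.0
        X = factors @ loadings + 0.3 * rng.standard_normal((2000, 12))
        result = pca_correlation(make_table(X))
        assert result.retained == 3

    def test_eigenvalue_sum_equals_feature_count_and_reconstruction(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((300, 12)) @ rng.standard_normal((12, 12))
        table = make_table(X)
        result = pca_correlation(table)
        assert result.eigenvalues.sum() == pytest.approx(12.0, abs=1e-8)
        V = result.loadings.to_numpy()
        recon = V @ np.diag(result.eigenvalues) @ V.T
        np.testing.assert_allclose(recon, np.corrcoef(X, rowvar=False), atol=1e-8)
        np.testing.assert_allclose(np.linalg.norm(V, axis=0), 1.0, atol=1e-10)

    def test_loading_sign_convention(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((200, 5))
        result = pca_correlation(make_table(X))
        V = result.loadings.to_numpy()
        for j in range(V.shape[1]):
            assert V[np.argmax(np.abs(V[:, j])), j] > 0

    def test_constant_column_error_names_column(self):
        X = np.random.default_rng(6).standard_normal((50, 3))
        X[:, 1] = 7.0
        with pytest.raises(ValueError, match="G"):
            pca_correlation(make_table(X))


class TestRelieff:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        n = 60
        labels = np.repeat([0, 1, 2], n // 3)
        X = rng.standard_normal((n, 4))
        X[:, 0] += 2.0 * labels  # informative feature
        table = make_table(X)
        ours = relieff(table, labels, k=3)
        oracle = brute_force_relieff(X, labels, k=3)
        np.testing.assert_allclose(
            [ours[c] for c in table.columns], oracle, atol=1e-12
        )

    def test_class_indicator_feature_gets_top_weight(self):
        rng = np.random.default_rng(8)
        n = 500
        labels = rng.integers(0, 2, n)
        X = rng.uniform(size=(n, 6))
        X[:, 2] = labels.astype(float)  # exact class indicator
        table = make_table(X)
        weights = relieff(table, labels, k=10, seed=0)
        assert rank_features(weights, 1) == [table.columns[2]]
        assert weights[table.columns[2]] == max(weights.values())

    def test_constant_feature_has_weight_exactly_zero(self):
        rng = np.random.default_rng(9)
        labels = np.repeat([0, 1], 30)
        X = rng.standard_normal((60, 3))
        X[:, 1] = 5.0
        weights = relieff(make_table(X), labels, k=5)
        assert weights[make_table(X).columns[1]] == 0.0

    def test_pure_noise_feature_weight_small_across_seeds(self):
        rng = np.random.default_rng(10)
        for seed in range(10):
            n = 500
            labels = rng.integers(0, 3, n)
            labels[:30] = np.arange(30) % 3  # guarantee class sizes > k
            X = rng.uniform(size=(n, 2))
            weights = relieff(make_table(X), labels, k=10, seed=seed)
            for w in weights.values():
                assert abs(w) < 0.05

    def test_weights_invariant_under_affine_feature_rescaling(self):
        rng = np.random.default_rng(11)
        labels = np.repeat([0, 1, 2], 20)
        X = rng.standard_normal((60, 4))
        w1 = relieff(make_table(X), labels, k=4, seed=1)
        X2 = X.copy()
        X2[:, 0] = 100.0 * X2[:, 0] - 7.0
        w2 = relieff(make_table(X2), labels, k=4, seed=1)
        for c in make_table(X).columns:
            assert w1[c] == pytest.approx(w2[c], abs=1e-12)

    def test_seed_reproducibility_and_bounds(self):
        rng = np.random.default_rng(12)
        labels = np.repeat([0, 1], 40)
        X = rng.standard_normal((80, 5))
        w1 = relieff(make_table(X), labels, k=5, n_iter=40, seed=3)
        w2 = relieff(make_table(X), labels, k=5, n_iter=40, seed=3)
        assert w1 == w2
        assert all(-1.0 <= v <= 1.0 for v in w1.values())

    def test_small_class_rejected(self):
        labels = np.array([0] * 5 + [1] * 50)
        X = np.random.default_rng(13).standard_normal((55, 3))
        with pytest.raises(ValueError, match="members"):
            relieff(make_table(X), labels, k=10)


class TestRankFeatures:
    def test_top3_selects_hue_saturation_a(self):
        weights = {c: 0.0 for c in CHANNELS}
        weights.update({"H": 0.3, "S": 0.2, "a": 0.1})
        assert rank_features(weights, 3) == ["H", "S", "a"]

    def test_all_equal_weights_fall_back_to_canonical_order(self):
        weights = {c: 0.5 for c in CHANNELS}
        assert rank_features(weights, 12) == list(CHANNELS)

    def test_full_ranking_is_a_permutation(self):
        rng = np.random.default_rng(14)
        weights = {c: float(rng.random()) for c in CHANNELS}
        ranked = rank_features(weights, 12)
        assert sorted(ranked) == sorted(CHANNELS)

    def test_top_n_beyond_feature_count_rejected(self):
        with pytest.raises(ValueError):
            rank_features({c: 0.0 for c in CHANNELS}, 13)
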