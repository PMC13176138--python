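import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brainaging.pls import (
    bootstrap_stability,
    crossval_score_correlation,
    fit_pls,
    per_marker_regressions,
    permutation_test,
    score_correlation,
)
from brainaging.synth import make_null_pair


def planted_rank1(n=1000, p=3, q=8, noise=0.3, seed=0):
    """X and Y sharing one latent direction; returns (X, Y, u, v)."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    u = rng.standard_normal(p)
    u /= np.linalg.norm(u)
    v = rng.standard_normal(q)
    v /= np.linalg.norm(v)
    X = np.outer(z, u) + noise * rng.standard_normal((n, p))
    Y = np.outer(z, v) + noise * rng.standard_normal((n, q))
    return X, Y, u, v


class TestFitPLS:
    def test_univariate_identity(self, rng):
        x = rng.standard_normal(200)
        model = fit_pls(x[:, None], x[:, None])
        assert abs(model.U[0, 0]) == pytest.approx(1.0)
        assert abs(model.V[0, 0]) == pytest.approx(1.0)
        np.testing.assert_allclose(model.covariance_explained, [1.0])
        assert score_correlation(model, 0) == pytest.approx(1.0)

    def test_rank1_recovery(self):
        X, Y, u, v = planted_rank1(n=2000, noise=0.2, seed=1)
        model = fit_pls(X, Y, scale=False)
        assert model.covariance_explained[0] > 0.9
        assert abs(model.U[:, 0] @ u) > 0.95
        assert abs(model.V[:, 0] @ v) > 0.95

    def test_svd_oracle_equivalence(self):
        # dense SVD of the explicitly formed cross-covariance matrix
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((60, 5))
            Y = rng.standard_normal((60, 8))
            model = fit_pls(X, Y, scale=False)
            Xc = X - X.mean(0)
            Yc = Y - Y.mean(0)
            R = np.zeros((5, 8))
            for i in range(5):  # brute-force cross-covariance
                for j in range(8):
                    R[i, j] = Xc[:, i] @ Yc[:, j] / (60 - 1)
            s_oracle = np.linalg.svd(R, compute_uv=False)
            np.testing.assert_allclose(model.singular_values, s_oracle, atol=1e-10)

    def test_covariance_explained_sums_to_one(self, rng):
        X = rng.standard_normal((100, 4))
        Y = rng.standard_normal((100, 7))
        model = fit_pls(X, Y)
        assert model.covariance_explained.sum() == pytest.approx(1.0, abs=1e-10)
        assert (np.diff(model.singular_values) <= 1e-12).all()
        np.testing.assert_allclose(np.linalg.norm(model.U, axis=0), 1.0, atol=1e-10)
        np.testing.assert_allclose(np.linalg.norm(model.V, axis=0), 1.0, atol=1e-10)

    def test_constant_column_named(self, rng):
        X = rng.standard_normal((50, 3))
        X[:, 1] = 4.2
        with pytest.raises(ValueError, match="flat"):
            fit_pls(X, rng.standard_normal((50, 4)), x_names=["a", "flat", "c"])

    def test_sign_anchor_positive(self):
        X, Y, _, _ = planted_rank1(seed=3)
        model = fit_pls(X, Y, sign_anchor=0)
        assert model.U[0, 0] >= 0

    def test_global_sign_flip_invariance(self):
        X, Y, _, _ = planted_rank1(n=500, seed=4)
        m1 = fit_pls(X, Y)
        m2 = fit_pls(-X, Y)  # flips the planted direction
        np.testing.assert_allclose(
            m1.covariance_explained, m2.covariance_explained, atol=1e-10
        )
        np.testing.assert_allclose(m1.singular_values, m2.singular_values, atol=1e-10)

    def test_needs_enough_rows(self, rng):
        with pytest.raises(ValueError, match="n > max"):
            fit_pls(rng.standard_normal((5, 6)), rng.standard_normal((5, 3)))

    def test_transform_matches_training_scores(self):
        X, Y, _, _ = planted_rank1(n=300, seed=5)
        model = fit_pls(X, Y)
        xs, ys = model.transform(X, Y)
        np.testing.assert_allclose(xs, model.imaging_scores, atol=1e-10)
        np.testing.assert_allclose(ys, model.clinical_scores, atol=1e-10)


class TestPermutation:
    def test_planted_signal_min_p(self):
        X, Y, _, _ = planted_rank1(n=800, noise=0.2, seed=6)
        res = permutation_test(X, Y, n_perm=200, seed=0)
        assert res.p_raw[0] == pytest.approx(1 / 201)
        assert res.n_permutations == 200

    def test_determinism(self):
        X, Y = make_null_pair(200, 3, 5, seed=1)
        r1 = permutation_test(X, Y, n_perm=150, seed=9)
        r2 = permutation_test(X, Y, n_perm=150, seed=9)
        np.testing.assert_array_equal(r1.p_raw, r2.p_raw)

    def test_low_perm_warns(self):
        X, Y = make_null_pair(100, 2, 3, seed=2)
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_test(X, Y, n_perm=50, seed=0)

    def test_p_in_valid_range(self):
        X, Y = make_null_pair(200, 3, 5, seed=3)
        res = permutation_test(X, Y, n_perm=150, seed=0)
        assert (res.p_raw > 1 / 151 - 1e-12).all()
        assert (res.p_raw <= 1.0).all()
        assert (res.p_fdr >= res.p_raw - 1e-12).all()

    def test_rotated_scheme_runs(self):
        X, Y, _, _ = planted_rank1(n=400, seed=7)
        res = permutation_test(X, Y, n_perm=150, seed=0, rotate=True)
        assert res.p_raw[0] == pytest.approx(1 / 151)


class TestBootstrap:
    def test_planted_signal_bsr_significant(self):
        # every X variable carries a substantial share of the latent
        rng = np.random.default_rng(8)
        n, p, q = 2000, 3, 8
        z = rng.standard_normal(n)
        u = np.ones(p) / np.sqrt(p)
        v = np.ones(q) / np.sqrt(q)
        X = np.outer(z, u) + 0.2 * rng.standard_normal((n, p))
        Y = np.outer(z, v) + 0.2 * rng.standard_normal((n, q))
        res = bootstrap_stability(X, Y, n_boot=200, seed=0)
        assert (np.abs(res.bootstrap_ratios[:, 0]) > 1.96).all()
        assert res.x_significant[:, 0].all()

    def test_null_variable_not_significant(self):
        # pure-noise imaging column appended to a planted-signal set
        hits_x, cover_y = 0, 0
        reps = 20
        for rep in range(reps):
            X, Y, _, _ = planted_rank1(n=600, noise=0.3, seed=100 + rep)
            rng = np.random.default_rng(999 + rep)
            Xa = np.column_stack([X, rng.standard_normal(len(X))])
            Ya = np.column_stack([Y, rng.standard_normal(len(Y))])
            res = bootstrap_stability(Xa, Ya, n_boot=200, seed=rep)
            hits_x += abs(res.bootstrap_ratios[-1, 0]) < 1.96
            cover_y += (res.clinical_ci_lo[-1, 0] <= 0 <= res.clinical_ci_hi[-1, 0])
        assert hits_x >= 0.9 * reps
        assert cover_y >= 0.9 * reps

    def test_zero_boot_errors(self):
        X, Y = make_null_pair(100, 2, 3, seed=0)
        with pytest.raises(ValueError):
            bootstrap_stability(X, Y, n_boot=0)

    def test_ci_ordering(self):
        X, Y, _, _ = planted_rank1(n=300, seed=9)
        res = bootstrap_stability(X, Y, n_boot=150, seed=0)
        assert (res.clinical_ci_lo <= res.clinical_ci_hi + 1e-12).all()

    def test_determinism(self):
        X, Y, _, _ = planted_rank1(n=300, seed=10)
        r1 = bootstrap_stability(X, Y, n_boot=100, seed=4)
        r2 = bootstrap_stability(X, Y, n_boot=100, seed=4)
        np.testing.assert_array_equal(r1.bootstrap_ratios, r2.bootstrap_ratios)


class TestScoreCorrelation:
    def test_identity_blocks(self, rng):
        x = rng.standard_normal(150)
        model = fit_pls(x[:, None], x[:, None])
        assert score_correlation(model, 0) == pytest.approx(1.0)

    def test_monotone_invariance(self):
        X, Y, _, _ = planted_rank1(n=400, seed=11)
        model = fit_pls(X, Y)
        r = score_correlation(model, 0)
        cubed = stats.spearmanr(
            model.imaging_scores[:, 0] ** 3, model.clinical_scores[:, 0]
        ).statistic
        assert r == pytest.approx(cubed)

    def test_out_of_range_lv(self):
        X, Y, _, _ = planted_rank1(n=200, seed=12)
        model = fit_pls(X, Y)
        with pytest.raises(IndexError):
            score_correlation(model, 99)


class TestCrossval:
    def test_strong_coupling(self):
        X, Y, _, _ = planted_rank1(n=1500, noise=0.05, seed=13)
        assert crossval_score_correlation(X, Y, k=10, seed=0) > 0.9

    def test_null_data_near_zero(self):
        X, Y = make_null_pair(2000, 3, 8, seed=14)
        assert abs(crossval_score_correlation(X, Y, k=10, seed=0)) < 0.05

    def test_determinism_and_k_check(self):
        X, Y, _, _ = planted_rank1(n=400, seed=15)
        assert crossval_score_correlation(X, Y, k=5, seed=3) == crossval_score_correlation(
            X, Y, k=5, seed=3
        )
        with pytest.raises(ValueError):
            crossval_score_correlation(X, Y, k=1)


class TestPerMarkerRegressions:
    def test_beta_recovery(self):
        rng = np.random.default_rng(16)
        n = 10_000
        marker = rng.standard_normal(n)
        outcome = 0.3 * marker + np.sqrt(1 - 0.09) * rng.standard_normal(n)
        table = per_marker_regressions(
            pd.DataFrame({"m": marker}), pd.DataFrame({"o": outcome})
        )
        assert table.loc[0, "beta"] == pytest.approx(0.30, abs=0.02)

    def test_self_regression_beta_one(self, rng):
        x = rng.standard_normal(500)
        table = per_marker_regressions(pd.DataFrame({"m": x}), pd.DataFrame({"o": x}))
        assert table.loc[0, "beta"] == pytest.approx(1.0)

    def test_null_not_significant(self):
        hits = 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(300 + rep)
            table = per_marker_regressions(
                pd.DataFrame({"m": rng.standard_normal(400)}),
                pd.DataFrame({"o": rng.standard_normal(400)}),
            )
            hits += table.loc[0, "p_fdr"] > 0.05
        assert hits >= 0.9 * reps

    def test_covariate_adjustment(self):
        rng = np.random.default_rng(17)
        n = 5000
        age = rng.uniform(50, 80, n)
        marker = 0.1 * age + rng.standard_normal(n)
        outcome = -0.05 * age + rng.standard_normal(n)  # only via age
        unadj = per_marker_regressions(
            pd.DataFrame({"m": marker}), pd.DataFrame({"o": outcome})
        )
        adj = per_marker_regressions(
            pd.DataFrame({"m": marker}), pd.DataFrame({"o": outcome}), covariates=age[:, None]
        )
        assert abs(adj.loc[0, "beta"]) < abs(unadj.loc[0, "beta"])
        assert abs(adj.loc[0, "beta"]) < 0.05
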