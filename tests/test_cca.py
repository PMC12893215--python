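import warnings

import numpy as np
import pytest
from scipy import stats

from melophys.cca import (
    fit_cca,
    loadings,
    permutation_pvalues,
    relative_covariance,
    surrogate_selection,
    wilks_test,
)


def planted_factor_data(rng, n=400, noise_sd=0.5):
    f = rng.standard_normal(n)
    u_dir = np.array([1.0, -1.0, 0.5, 0.0])
    u_dir /= np.linalg.norm(u_dir)
    v_dir = np.array([0.5, 1.0, -1.0])
    v_dir /= np.linalg.norm(v_dir)
    x = np.outer(f, u_dir) + noise_sd * rng.standard_normal((n, 4))
    y = np.outer(f, v_dir) + noise_sd * rng.standard_normal((n, 3))
    return x, y, u_dir, v_dir


class TestFitCCA:
    def test_identity_coupling_all_r_one(self, rng):
        x = rng.standard_normal((150, 4))
        res = fit_cca(x, x.copy())
        np.testing.assert_allclose(res.correlations, 1.0, atol=1e-8)

    def test_planted_factor_recovered(self, rng):
        x, y, u_dir, _ = planted_factor_data(rng)
        res = fit_cca(x, y)
        w = res.x_weights[:, 0] / np.linalg.norm(res.x_weights[:, 0])
        assert abs(np.dot(w, u_dir)) >= 0.95

    def test_null_r1_below_rao_quantile(self):
        # [oracle] Rao's F approximation of the null distribution of r1
        n, p, q = 500, 3, 3
        hits = 0
        reps = 40
        for i in range(reps):
            rng = np.random.default_rng(i)
            res = fit_cca(rng.standard_normal((n, p)), rng.standard_normal((n, q)))
            # null 95% quantile of the largest canonical correlation via
            # Bartlett chi2 inversion on Lambda_1
            df = p * q
            chi_crit = stats.chi2.ppf(0.95, df)
            lam_crit = np.exp(-chi_crit / (n - 1 - (p + q + 1) / 2))
            # treat all correlation mass as r1 for a conservative bound
            r1_crit = np.sqrt(1 - lam_crit)
            if res.correlations[0] < r1_crit:
                hits += 1
        assert hits / reps >= 0.9

    def test_orthogonality(self, rng):
        x = rng.standard_normal((200, 5))
        y = rng.standard_normal((200, 4)) + 0.3 * x[:, :4]
        res = fit_cca(x, y)
        cu = np.corrcoef(res.x_scores.T) - np.eye(res.k)
        cv = np.corrcoef(res.y_scores.T) - np.eye(res.k)
        assert np.max(np.abs(cu)) < 1e-8
        assert np.max(np.abs(cv)) < 1e-8

    def test_scale_invariance(self, rng):
        x = rng.standard_normal((200, 4))
        y = rng.standard_normal((200, 3)) + 0.4 * x[:, :3]
        res1 = fit_cca(x, y)
        x2 = x.copy()
        x2[:, 1] *= 37.5
        res2 = fit_cca(x2, y)
        np.testing.assert_allclose(res1.correlations, res2.correlations, atol=1e-8)
        np.testing.assert_allclose(res1.x_loadings, res2.x_loadings, atol=1e-8)

    def test_rank_deficient_column_dropped(self, rng):
        x = rng.standard_normal((100, 3))
        x[:, 2] = 5.0  # constant
        y = rng.standard_normal((100, 2))
        with pytest.warns(UserWarning, match="zero-variance"):
            res = fit_cca(x, y)
        assert len(res.x_columns) == 2

    def test_ridge_warning_when_underdetermined(self, rng):
        x = rng.standard_normal((10, 6))
        y = rng.standard_normal((10, 5))
        with pytest.warns(UserWarning, match="ridge"):
            res = fit_cca(x, y)
        assert res.flags["ridge"]

    def test_sign_canonicalization(self, rng):
        x, y, _, _ = planted_factor_data(rng)
        res = fit_cca(x, y)
        for i in range(res.k):
            j = np.argmax(np.abs(res.x_loadings[:, i]))
            assert res.x_loadings[j, i] > 0

    def test_anti_coupled_pair_opposite_sign_loadings(self, rng):
        n = 300
        f = rng.standard_normal(n)
        x = np.column_stack([f, rng.standard_normal(n)]) + 0.3 * rng.standard_normal((n, 2))
        y = np.column_stack([-f, rng.standard_normal(n)]) + 0.3 * rng.standard_normal((n, 2))
        res = fit_cca(x, y)
        assert res.x_loadings[0, 0] * res.y_loadings[0, 0] < 0


class TestLoadings:
    def test_single_column_loading_is_one(self, rng):
        x = rng.standard_normal((100, 1))
        y = rng.standard_normal((100, 2)) + 0.5 * x
        res = fit_cca(x, y)
        xl, _ = loadings(res)
        assert xl.iloc[0, 0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_brute_force(self, rng):
        x = rng.standard_normal((150, 4))
        y = rng.standard_normal((150, 3)) + 0.5 * x[:, :3]
        res = fit_cca(x, y)
        for j in range(4):
            for i in range(res.k):
                oracle = np.corrcoef(x[:, j], res.x_scores[:, i])[0, 1]
                assert res.x_loadings[j, i] == pytest.approx(oracle, abs=1e-10)

    def test_bounded_by_one(self, rng):
        x = rng.standard_normal((80, 5))
        y = rng.standard_normal((80, 4))
        res = fit_cca(x, y)
        assert np.all(np.abs(res.x_loadings) <= 1 + 1e-12)
        assert np.all(np.abs(res.y_loadings) <= 1 + 1e-12)


class TestRelativeCovariance:
    def test_single_nonzero(self):
        res = _fake_result([0.8, 0.0, 0.0])
        np.testing.assert_allclose(relative_covariance(res), [100.0, 0.0, 0.0])

    def test_equal_split(self):
        res = _fake_result([0.5, 0.5, 0.5])
        np.testing.assert_allclose(relative_covariance(res), [100 / 3] * 3)

    def test_sums_to_100(self, rng):
        x = rng.standard_normal((120, 4))
        y = rng.standard_normal((120, 3)) + 0.4 * x[:, :3]
        res = fit_cca(x, y)
        assert relative_covariance(res).sum() == pytest.approx(100.0, abs=1e-9)


def _fake_result(correlations):
    from melophys.cca import CCAResult

    r = np.asarray(correlations, dtype=float)
    k = len(r)
    return CCAResult(
        x_columns=[f"x{i}" for i in range(k)], y_columns=[f"y{i}" for i in range(k)],
        n=100, correlations=r, x_weights=np.eye(k), y_weights=np.eye(k),
        x_scores=np.zeros((100, k)), y_scores=np.zeros((100, k)),
        x_loadings=np.eye(k), y_loadings=np.eye(k),
    )


class TestWilks:
    def test_all_zero_correlations(self):
        p = wilks_test([0.0, 0.0], n=100, p=3, q=2)
        np.testing.assert_allclose(p, 1.0)

    def test_perfect_correlation_p_zero(self):
        p = wilks_test([0.999999, 0.1], n=100, p=3, q=2)
        assert p[0] < 1e-10

    def test_matches_independent_computation(self):
        # [oracle] hand computation of Bartlett's approximation on a 3x2 fixture
        r = np.array([0.6, 0.3])
        n, p, q = 50, 3, 2
        lam1 = (1 - 0.6**2) * (1 - 0.3**2)
        chi1 = -(n - 1 - (p + q + 1) / 2) * np.log(lam1)
        expected1 = stats.chi2.sf(chi1, p * q)
        lam2 = 1 - 0.3**2
        chi2_ = -(n - 1 - (p + q + 1) / 2) * np.log(lam2)
        expected2 = stats.chi2.sf(chi2_, (p - 1) * (q - 1))
        out = wilks_test(r, n, p, q)
        assert out[0] == pytest.approx(expected1, rel=1e-12)
        assert out[1] == pytest.approx(expected2, rel=1e-12)


class TestSurrogateSelection:
    def test_null_retains_nothing(self):
        retained_any = 0
        reps = 30
        for i in range(reps):
            rng = np.random.default_rng(i)
            x = rng.standard_normal((120, 4))
            y = rng.standard_normal((120, 3))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ret = surrogate_selection(x, y, n_surrogates=40, seed=i)
            retained_any += ret.any()
        assert 1 - retained_any / reps >= 0.9

    def test_planted_coupling_retains_first(self):
        hits = 0
        reps = 20
        for i in range(reps):
            rng = np.random.default_rng(100 + i)
            x, y, _, _ = planted_factor_data(rng, n=300)
            ret = surrogate_selection(x, y, n_surrogates=40, seed=i)
            if ret[0] and not ret[1:].any():
                hits += 1
        assert hits / reps >= 0.9

    def test_retention_monotone_in_effect_size(self):
        rng = np.random.default_rng(7)
        n = 300
        f = rng.standard_normal(n)
        ex = rng.standard_normal((n, 3))
        ey = rng.standard_normal((n, 3))
        retained_flags = []
        for strength in (0.5, 1.0, 2.0):
            x = strength * np.outer(f, [1, 0.5, -0.5]) + ex
            y = strength * np.outer(f, [0.5, 1, 0.5]) + ey
            ret = surrogate_selection(x, y, n_surrogates=40, seed=1)
            retained_flags.append(bool(ret[0]))
        # once retained, stays retained as coupling strengthens
        for weaker, stronger in zip(retained_flags, retained_flags[1:]):
            assert stronger >= weaker
        assert retained_flags[-1]

    def test_too_few_surrogates(self, rng):
        with pytest.raises(Exception):
            surrogate_selection(rng.standard_normal((50, 2)),
                                rng.standard_normal((50, 2)), n_surrogates=5)


class TestPermutationPvalues:
    def test_bounds(self, rng):
        x = rng.standard_normal((60, 3))
        y = rng.standard_normal((60, 2))
        p = permutation_pvalues(x, y, n_perm=49, seed=0)
        assert np.all(p >= 1 / 50) and np.all(p <= 1.0)

    def test_perfect_coupling_minimum_p(self, rng):
        x = rng.standard_normal((100, 2))
        p = permutation_pvalues(x, x.copy(), n_perm=99, seed=0)
        assert p[0] == pytest.approx(1 / 100)

    def test_null_uniformity_reduced(self):
        # reduced calibration: 60 null replicates, n_perm = 49
        pvals = []
        for i in range(60):
            rng = np.random.default_rng(i)
            x = rng.standard_normal((80, 2))
            y = rng.standard_normal((80, 2))
            pvals.append(permutation_pvalues(x, y, n_perm=49, seed=i)[0])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
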