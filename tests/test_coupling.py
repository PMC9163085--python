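"""Frame-wise multilinear coupling model, static coupling, dominance."""

import numpy as np
import pytest

from sfcoupling import (
    PredictorSet,
    dominance_analysis,
    dynamic_coupling,
    edge_timeseries,
    fit_ols,
    node_design,
    spearman_rank_coupling,
    static_coupling,
    zscore,
)


class TestNodeDesign:
    def test_skips_diagonal(self, predictors20):
        i = 2
        x = node_design(predictors20, i)
        assert x.shape == (19, 4)
        mask = np.arange(20) != i
        np.testing.assert_array_equal(x[:, 1], predictors20.dist[i, mask])
        np.testing.assert_array_equal(x[:, 2], predictors20.spl[i, mask])
        np.testing.assert_array_equal(x[:, 3], predictors20.cmc[i, mask])
        assert np.all(x[:, 0] == 1.0)

    def test_out_of_range(self, predictors20):
        with pytest.raises(IndexError):
            node_design(predictors20, 20)


class TestFitOls:
    def test_exact_fit_recovery(self, predictors20):
        x = node_design(predictors20, 0)
        beta = np.array([0.3, -0.01, 0.5, 2.0])
        fit = fit_ols(x, x @ beta)
        np.testing.assert_allclose(fit.beta, beta, atol=1e-8)
        assert fit.r2 == pytest.approx(1.0, abs=1e-8)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-8)

    def test_adjusted_r2_identity(self, predictors20, rng):
        x = node_design(predictors20, 3)
        fit = fit_ols(x, rng.normal(size=len(x)))
        n, p = fit.n_obs, fit.n_pred
        expected = 1 - (1 - fit.r2) * (n - 1) / (n - p - 1)
        assert fit.adj_r2 == pytest.approx(expected, abs=1e-12)
        assert 0.0 <= fit.r2 <= 1.0

    def test_null_calibration(self, rng):
        """Adjusted R^2 is (nearly) unbiased under the null."""
        x = np.column_stack([np.ones(99), rng.normal(size=(99, 3))])
        vals = [fit_ols(x, rng.normal(size=99)).adj_r2 for _ in range(300)]
        assert abs(np.mean(vals)) < 0.02

    def test_constant_response_error(self, predictors20):
        x = node_design(predictors20, 0)
        with pytest.raises(ValueError, match="variance"):
            fit_ols(x, np.full(len(x), 0.7))

    def test_collinear_design_error(self, rng):
        col = rng.normal(size=30)
        x = np.column_stack([np.ones(30), col, 2 * col, rng.normal(size=30)])
        with pytest.raises(ValueError, match="collinear"):
            fit_ols(x, rng.normal(size=30))

    def test_matches_statsmodels(self, predictors20, rng):
        sm = pytest.importorskip("statsmodels.api")
        x = node_design(predictors20, 5)
        y = rng.normal(size=len(x)) + 0.3 * x[:, 3]
        fit = fit_ols(x, y)
        ref = sm.OLS(y, x).fit()
        assert fit.r2 == pytest.approx(ref.rsquared, abs=1e-10)
        assert fit.adj_r2 == pytest.approx(ref.rsquared_adj, abs=1e-10)
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-8)


class TestDynamicCoupling:
    def test_exact_linear_frames(self, predictors20):
        n, t = 20, 7
        ets = np.empty((n, n, t))
        base = 0.1 * predictors20.dist + 1.4 * predictors20.spl - 0.8 * predictors20.cmc
        for k in range(t):
            ets[:, :, k] = (k + 1) * base
        cm = dynamic_coupling(predictors20, ets)
        assert cm.values.shape == (n, t)
        np.testing.assert_allclose(cm.values, 1.0, atol=1e-8)

    def test_degenerate_frame_flagged(self, predictors20, rng):
        n = 20
        ets = rng.normal(size=(n, n, 4))
        ets = ets + np.swapaxes(ets, 0, 1)
        ets[:, :, 2] = 0.42  # constant frame: all profiles degenerate
        with pytest.warns(UserWarning, match="degenerate"):
            cm = dynamic_coupling(predictors20, ets)
        assert cm.degenerate_frames == n
        assert np.all(np.isnan(cm.values[:, 2]))
        assert np.all(np.isfinite(cm.values[:, [0, 1, 3]]))

    def test_node_permutation_equivariance(self, geometry20, sc20, predictors20, rng):
        z = zscore(rng.normal(size=(20, 50)))
        ets = edge_timeseries(z)
        cm = dynamic_coupling(predictors20, ets)
        perm = rng.permutation(20)
        pred_p = PredictorSet(
            dist=predictors20.dist[np.ix_(perm, perm)],
            spl=predictors20.spl[np.ix_(perm, perm)],
            cmc=predictors20.cmc[np.ix_(perm, perm)],
        )
        cm_p = dynamic_coupling(pred_p, ets[np.ix_(perm, perm)])
        np.testing.assert_allclose(cm_p.values, cm.values[perm], atol=1e-10)


class TestStaticCoupling:
    def test_exact_linear_profile(self, predictors20):
        fc = 0.2 * predictors20.dist - 0.5 * predictors20.spl + 1.1 * predictors20.cmc
        vals = static_coupling(predictors20, fc)
        assert vals.shape == (20,)
        np.testing.assert_allclose(vals, 1.0, atol=1e-8)

    def test_nonlinearity_of_r2(self, predictors20, rng):
        """Mean-over-time of frame-wise coupling differs from coupling of the mean."""
        z = zscore(rng.normal(size=(20, 80)))
        ets = edge_timeseries(z)
        dyn = dynamic_coupling(predictors20, ets)
        stat_of_mean = static_coupling(predictors20, ets.mean(axis=2))
        assert not np.allclose(np.nanmean(dyn.values, axis=1), stat_of_mean, atol=1e-3)


class TestSpearmanRankCoupling:
    def test_monotone_profiles(self):
        sc = np.array(
            [
                [0.0, 1.0, 2.0, 3.0],
                [1.0, 0.0, 1.0, 1.0],
                [2.0, 1.0, 0.0, 1.0],
                [3.0, 1.0, 1.0, 0.0],
            ]
        )
        fc = np.zeros((4, 4))
        fc[0] = [0.0, 0.1, 0.2, 0.3]
        fc[:, 0] = fc[0]
        vals = spearman_rank_coupling(sc, fc)
        assert vals[0] == pytest.approx(1.0)
        vals_rev = spearman_rank_coupling(sc, -fc)
        assert vals_rev[0] == pytest.approx(-1.0)

    def test_midrank_ties(self):
        sc = np.zeros((4, 4))
        sc[0, 1:] = [1.0, 1.0, 2.0]
        sc[1:, 0] = sc[0, 1:]
        sc[1, 2] = sc[2, 1] = sc[1, 3] = sc[3, 1] = sc[2, 3] = sc[3, 2] = 1.0
        fc = np.zeros((4, 4))
        fc[0, 1:] = [5.0, 5.0, 9.0]
        fc[1:, 0] = fc[0, 1:]
        assert spearman_rank_coupling(sc, fc)[0] == pytest.approx(1.0)

    def test_too_few_connections_missing(self):
        rng = np.random.default_rng(3)
        sc = rng.uniform(0.5, 2.0, size=(5, 5))
        sc = (sc + sc.T) / 2
        np.fill_diagonal(sc, 0.0)
        sc[0, :] = sc[:, 0] = 0.0
        sc[0, 1] = sc[1, 0] = 1.0  # node 0 has a single connection
        fc = rng.normal(size=(5, 5))
        fc = (fc + fc.T) / 2
        with pytest.warns(UserWarning, match="rank coupling undefined"):
            vals = spearman_rank_coupling(sc, fc)
        assert np.isnan(vals[0])
        assert np.all(np.isfinite(vals[1:]))


class TestDominanceAnalysis:
    def test_sums_to_full_model_r2(self, predictors20, rng):
        x = node_design(predictors20, 4)
        y = rng.normal(size=len(x)) + 0.2 * x[:, 1]
        dom = dominance_analysis(x, y)
        full = fit_ols(x, y).r2
        assert dom.sum() == pytest.approx(full, abs=1e-10)
        assert np.all(dom >= -1e-12)

    def test_orthogonal_design_attribution(self, rng):
        # orthonormal predictors: dominance equals the marginal R^2 share
        raw = rng.normal(size=(200, 3))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        x = np.column_stack([np.ones(200), q])
        y = 2.0 * q[:, 0] + 1.0 * q[:, 1]  # predictor 3 is pure null
        dom = dominance_analysis(x, y)
        assert dom[2] < 1e-10
        marg0 = fit_ols(x[:, [0, 1]], y).r2
        marg1 = fit_ols(x[:, [0, 2]], y).r2
        assert dom[0] == pytest.approx(marg0, abs=1e-10)
        assert dom[1] == pytest.approx(marg1, abs=1e-10)

    def test_noise_response_small_nonnegative(self, predictors20, rng):
        x = node_design(predictors20, 9)
        doms = np.array(
            [dominance_analysis(x, rng.normal(size=len(x))) for _ in range(50)]
        )
        assert np.all(doms >= -1e-12)
        assert doms.mean() < 0.2
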