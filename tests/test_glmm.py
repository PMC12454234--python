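"""Random-intercept logistic GLMM: quadrature accuracy, degenerate cases,
likelihood invariances and parameter recovery."""

import numpy as np
import pytest
from scipy.special import expit

from pseudorr.data import ClusteredDataset, DataError, ModelSpec
from pseudorr.glmm import (
    SeparationError,
    cluster_marginal_loglik,
    fit_logistic_glmm,
    fit_plain_logistic,
)


def brute_force_loglik(y, lin, tau, n_grid=100_001, half_width=10.0):
    """Trapezoid integration of the marginal likelihood over eta."""
    eta = np.linspace(-half_width * tau, half_width * tau, n_grid)
    ll = np.zeros_like(eta)
    for yi, li in zip(y, lin):
        ll += yi * np.log(expit(li + eta)) + (1 - yi) * np.log(1 - expit(li + eta))
    dens = np.exp(ll - eta**2 / (2 * tau**2)) / np.sqrt(2 * np.pi * tau**2)
    return float(np.log(np.trapezoid(dens, eta)))


class TestClusterMarginalLoglik:
    def test_single_bernoulli_at_zero(self, slope_spec):
        ds = ClusteredDataset.from_arrays([1], [1.0], {"x": [0.0]})
        assert cluster_marginal_loglik(ds, [0.0], 0.0, spec=slope_spec) == \
            pytest.approx(np.log(0.5), abs=1e-12)

    def test_tau_zero_is_bernoulli_sum(self, slope_spec):
        ds = ClusteredDataset.from_arrays(
            [1] * 4, [1.0, 0.0, 1.0, 1.0], {"x": [0.2, -0.5, 1.0, 0.0]})
        lin = np.array([0.2, -0.5, 1.0, 0.0]) * 0.7
        expected = float(np.sum(
            np.where(ds.df.y == 1, np.log(expit(lin)), np.log(1 - expit(lin)))))
        got = cluster_marginal_loglik(ds, [0.7], 0.0, spec=slope_spec)
        assert got == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("beta,tau", [
        (0.5, 0.1), (1.0, 0.8), (-0.7, 1.5), (0.0, 2.5), (2.0, 0.3),
    ])
    def test_matches_brute_force_integration(self, beta, tau, slope_spec):
        """AGQ equals dense trapezoid quadrature to 6 significant digits on
        clusters of up to 3 rows, across a (beta, tau) grid."""
        for y, x in [([1.0, 0.0], [0.3, -0.1]),
                     ([1.0, 1.0, 0.0], [0.3, -0.1, 0.8]),
                     ([0.0], [1.2])]:
            ds = ClusteredDataset.from_arrays([1] * len(y), y, {"x": x})
            got = cluster_marginal_loglik(ds, [beta], tau, n_nodes=25,
                                          spec=slope_spec)
            want = brute_force_loglik(np.array(y), np.array(x) * beta, tau)
            assert got == pytest.approx(want, rel=1e-6)

    def test_quadrature_converges_by_25_nodes(self, small_cluster, slope_spec):
        ref = cluster_marginal_loglik(small_cluster, [1.0], 0.8, n_nodes=50,
                                      spec=slope_spec)
        errs = [abs(cluster_marginal_loglik(small_cluster, [1.0], 0.8,
                                            n_nodes=k, spec=slope_spec) - ref)
                for k in range(1, 26)]
        assert errs[-1] < 1e-6
        assert all(b <= a + 1e-12 for a, b in zip(errs, errs[1:]))

    def test_tau_boundary_continuity(self, small_cluster, slope_spec):
        at_zero = cluster_marginal_loglik(small_cluster, [1.0], 0.0,
                                          spec=slope_spec)
        near_zero = cluster_marginal_loglik(small_cluster, [1.0], 1e-6,
                                            spec=slope_spec)
        assert near_zero == pytest.approx(at_zero, abs=1e-9)

    def test_nonfinite_predictor_names_row(self, slope_spec):
        ds = ClusteredDataset.from_arrays([1, 1], [1.0, 0.0], {"x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="row"):
            cluster_marginal_loglik(ds, [np.inf], 0.5, spec=slope_spec)

    def test_rejects_empty_and_bad_args(self, small_cluster, slope_spec):
        with pytest.raises(ValueError):
            cluster_marginal_loglik(small_cluster, [1.0], -0.5, spec=slope_spec)
        with pytest.raises(ValueError):
            cluster_marginal_loglik(small_cluster, [1.0], 0.5, n_nodes=0,
                                    spec=slope_spec)


class TestPlainLogistic:
    def test_intercept_only_closed_form(self):
        ds = ClusteredDataset.from_arrays(
            np.arange(100), np.r_[np.ones(40), np.zeros(60)])
        fit = fit_plain_logistic(ds, ModelSpec())
        assert fit.beta[0] == pytest.approx(np.log(40 / 60), abs=1e-10)
        assert fit.tau == 0.0 and fit.boundary_tau

    def test_two_by_two_table_closed_form(self):
        # exposed: 10 events / 20 non-events; unexposed: 5 / 25
        y = np.r_[np.ones(10), np.zeros(20), np.ones(5), np.zeros(25)]
        x = np.r_[np.ones(30), np.zeros(30)]
        ds = ClusteredDataset.from_arrays(np.arange(60), y, {"x": x})
        fit = fit_plain_logistic(ds, ModelSpec(covariates=["x"]))
        assert fit.coef("x") == pytest.approx(np.log(2.5), abs=1e-8)

    def test_matches_statsmodels(self, glmm_sim):
        sm = pytest.importorskip("statsmodels.api")
        ds = glmm_sim(N=150, tau=0.0, seed=3)
        fit = fit_plain_logistic(ds, ModelSpec(covariates=["x"]))
        X = sm.add_constant(ds.df["x"].to_numpy())
        oracle = sm.Logit(ds.df["y"].to_numpy(), X).fit(disp=0)
        np.testing.assert_allclose(fit.beta, oracle.params, atol=1e-6)

    def test_loglik_equals_cluster_sum_at_tau_zero(self, glmm_sim):
        ds = glmm_sim(N=20, tau=0.0, seed=5)
        spec = ModelSpec(covariates=["x"])
        fit = fit_plain_logistic(ds, spec)
        total = 0.0
        for _, sub in ds.df.groupby("cluster"):
            total += cluster_marginal_loglik(
                ClusteredDataset(sub, validate=False), fit.beta, 0.0, spec=spec)
        assert fit.loglik == pytest.approx(total, abs=1e-8)

    def test_separation_raises(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        x = y.copy()  # perfect separation
        ds = ClusteredDataset.from_arrays(np.arange(20), y, {"x": x})
        with pytest.raises(SeparationError):
            fit_plain_logistic(ds, ModelSpec(covariates=["x"]))


class TestFitLogisticGLMM:
    def test_tau_zero_data_degenerates_to_plain_mle(self, glmm_sim):
        """On data without cluster effects the GLMM collapses to the plain
        logistic MLE with the boundary flagged.  (Under a true zero variance
        component the ML estimate sits on the boundary in about half of all
        draws; the seed picks a draw from that half.)"""
        ds = glmm_sim(N=100, tau=0.0, seed=3)
        spec = ModelSpec(covariates=["x"])
        fit = fit_logistic_glmm(ds, spec)
        plain = fit_plain_logistic(ds, spec)
        assert fit.boundary_tau and fit.tau == 0.0
        np.testing.assert_allclose(fit.beta, plain.beta, atol=1e-4)
        assert fit.loglik == pytest.approx(plain.loglik, abs=1e-6)

    def test_duplicating_clusters_preserves_estimates(self, glmm_sim):
        ds = glmm_sim(N=60, tau=0.8, seed=7)
        spec = ModelSpec(covariates=["x"])
        base = fit_logistic_glmm(ds, spec)
        assert not base.boundary_tau  # need an interior optimum to be informative
        k = 3
        dfs = []
        for r in range(k):
            d = ds.df.copy()
            d["cluster"] = d["cluster"].astype(str) + f"_rep{r}"
            dfs.append(d)
        import pandas as pd

        big = ClusteredDataset(pd.concat(dfs, ignore_index=True))
        dup = fit_logistic_glmm(big, spec)
        np.testing.assert_allclose(dup.beta, base.beta, atol=2e-4)
        assert dup.tau == pytest.approx(base.tau, abs=2e-4)
        assert dup.loglik == pytest.approx(k * base.loglik, rel=1e-6)

    def test_parameter_recovery(self, glmm_sim):
        """500 clusters x 4 rows from tau=1, beta=(-1, 0.5): estimates land
        within Monte-Carlo range of the truth."""
        ds = glmm_sim(N=500, beta=(-1.0, 0.5), tau=1.0, seed=1)
        fit = fit_logistic_glmm(ds, ModelSpec(covariates=["x"]))
        assert fit.converged
        assert abs(fit.tau - 1.0) < 0.15
        # 3 x asymptotic SEs (~0.08 intercept, ~0.065 slope) at this size
        assert abs(fit.beta[0] - (-1.0)) < 0.24
        assert abs(fit.beta[1] - 0.5) < 0.20

    def test_row_permutation_invariance(self, glmm_sim):
        ds = glmm_sim(N=50, tau=0.8, seed=11)
        spec = ModelSpec(covariates=["x"])
        base = fit_logistic_glmm(ds, spec)
        rng = np.random.default_rng(0)
        perm = ClusteredDataset(
            ds.df.iloc[rng.permutation(len(ds.df))].reset_index(drop=True))
        shuf = fit_logistic_glmm(perm, spec)
        np.testing.assert_allclose(shuf.beta, base.beta, atol=1e-6)
        assert shuf.tau == pytest.approx(base.tau, abs=1e-6)

    def test_single_outcome_value_rejected(self):
        ds = ClusteredDataset.from_arrays([1, 2], [1.0, 1.0])
        with pytest.raises(ValueError, match="both outcome values"):
            fit_logistic_glmm(ds, ModelSpec())
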