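import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal, norm, poisson

from exomir import (
    ModelConfig,
    SimulationParams,
    StudyDesign,
    fdr_adjust,
    fit_mir,
    marginal_loglik,
    run_de_analysis,
    simulate_counts,
)
from exomir import test_contrasts as wald_contrasts
from conftest import bh_oracle

X1 = [[1.0, 0.0, 0.0]]
X2 = [[1.0, 0.0, 0.0], [1.0, 0.0, 0.0]]


def dense_grid_pair_loglik(y, eta, sigma2, rho, n=3001, half=6.0):
    """Brute-force 2-D trapezoid integration over u in [-6 sigma, 6 sigma]^2."""
    s = np.sqrt(sigma2)
    u = np.linspace(-half * s, half * s, n)
    U1, U2 = np.meshgrid(u, u, indexing="ij")
    dens = multivariate_normal([0, 0], sigma2 * np.array([[1, rho], [rho, 1]])).pdf(
        np.dstack([U1, U2])
    )
    lik = (
        poisson.pmf(y[0], np.exp(eta[0] + U1))
        * poisson.pmf(y[1], np.exp(eta[1] + U2))
        * dens
    )
    du = u[1] - u[0]
    return np.log(np.trapezoid(np.trapezoid(lik, dx=du, axis=1), dx=du))


class TestMarginalLoglik:
    def test_singleton_sigma0_is_poisson_pmf(self):
        ll = marginal_loglik([3], X1, 0.0, [np.log(4), 0, 0], 0.0, 0.0)
        assert ll == pytest.approx(poisson.logpmf(3, 4))  # ~ -1.6329
        assert ll == pytest.approx(-1.6329, abs=1e-4)

    def test_pair_rho0_factorizes(self):
        pair = marginal_loglik([3, 5], X2, 0.0, [np.log(4), 0, 0], 0.25, 0.0)
        s1 = marginal_loglik([3], X1, 0.0, [np.log(4), 0, 0], 0.25, 0.0)
        s2 = marginal_loglik([5], X1, 0.0, [np.log(4), 0, 0], 0.25, 0.0)
        assert pair == pytest.approx(s1 + s2, abs=1e-10)

    @pytest.mark.parametrize(
        "y,beta0,sigma2,rho",
        [
            ((3, 5), np.log(4), 0.25, 0.5),
            ((0, 7), np.log(2), 0.5, -0.3),
            ((40, 25), np.log(30), 0.09, 0.8),
        ],
    )
    def test_pair_matches_dense_grid(self, y, beta0, sigma2, rho):
        ll = marginal_loglik(list(y), X2, 0.0, [beta0, 0, 0], sigma2, rho)
        oracle = dense_grid_pair_loglik(np.array(y), np.array([beta0, beta0]), sigma2, rho)
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_quadrature_converged_at_default_nodes(self):
        args = ([3, 5], X2, 0.0, [np.log(4), 0, 0], 0.25, 0.5)
        assert marginal_loglik(*args, n_nodes=20) == pytest.approx(
            marginal_loglik(*args, n_nodes=40), abs=1e-8
        )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            marginal_loglik([1], X1, 0.0, [0, 0, 0], -0.1, 0.0)
        with pytest.raises(ValueError):
            marginal_loglik([1, 1], X2, 0.0, [0, 0, 0], 0.1, 1.0)
        with pytest.raises(ValueError):
            marginal_loglik([-1], X1, 0.0, [0, 0, 0], 0.1, 0.0)


class TestFitMir:
    def test_sigma0_data_matches_poisson_glm(self, tiny_samples):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        groups = tiny_samples.table["group"]
        lam = np.where(groups == "PRE", 30, np.where(groups == "POST_NOHRT", 45, 60))
        y = rng.poisson(lam).astype(float)
        fit = fit_mir(pd.Series(y, index=tiny_samples.sample_ids), tiny_samples, mir_id="m")
        X = np.column_stack(
            [np.ones(len(y)), groups == "POST_NOHRT", groups == "POST_HRT"]
        ).astype(float)
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        est = np.array([fit.beta0, fit.beta_nohrt, fit.beta_hrt])
        np.testing.assert_allclose(est, ref.params, atol=1e-4)

    def test_all_zero_mir_is_skip_signal(self, tiny_samples):
        assert fit_mir(np.zeros(9), tiny_samples, mir_id="z") is None

    def test_sample_order_permutation_invariance(self, tiny_samples):
        d = StudyDesign(n_singletons=3, n_pairs=3, n_mirs=1)
        cm, st_ = simulate_counts(d, SimulationParams([np.log(80)], sigma2=0.2, rho=0.5, seed=2))
        y = cm.counts.iloc[0]
        f1 = fit_mir(y, st_, mir_id="m")
        perm = y.sample(frac=1.0, random_state=1)
        f2 = fit_mir(perm, st_, mir_id="m")
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)
        assert f1.beta_hrt == pytest.approx(f2.beta_hrt, abs=1e-6)

    def test_loglik_not_worse_than_start(self):
        # monotone optimizer acceptance on a hard low-count miR
        d = StudyDesign(n_singletons=4, n_pairs=4, n_mirs=1)
        cm, st_ = simulate_counts(d, SimulationParams([0.3], sigma2=1.5, rho=0.3, seed=9))
        fit = fit_mir(cm.counts.iloc[0], st_, mir_id="m")
        assert np.isfinite(fit.loglik)
        assert fit.sigma2 >= 0 and abs(fit.rho) < 1

    def test_boundary_sigma2_reports_unidentified_rho(self, tiny_samples):
        rng = np.random.default_rng(1)
        y = rng.poisson(50, size=9).astype(float)  # pure Poisson data
        fit = fit_mir(pd.Series(y, index=tiny_samples.sample_ids), tiny_samples, mir_id="m")
        if fit.sigma2_at_boundary:
            assert fit.rho == 0.0 and not fit.rho_identified


class TestConsistency:
    def _errors(self, n_pairs, n_rep, seed0):
        d = StudyDesign(n_singletons=0, n_pairs=n_pairs, n_mirs=1)
        errs = []
        for i in range(n_rep):
            p = SimulationParams([np.log(300)], sigma2=0.3, rho=0.5, seed=seed0 + i)
            cm, st_ = simulate_counts(d, p)
            f = fit_mir(cm.counts.iloc[0], st_, mir_id="m")
            errs.append((f.sigma2 - 0.3, f.rho - 0.5))
        return np.array(errs)

    def test_variance_parameter_rmse_shrinks_with_pair_count(self):
        # sigma2-hat and rho-hat concentrate on the truth as pairs grow
        small = self._errors(100, 12, seed0=500)
        large = self._errors(1000, 12, seed0=900)
        for j in range(2):
            rmse_small = np.sqrt((small[:, j] ** 2).mean())
            rmse_large = np.sqrt((large[:, j] ** 2).mean())
            assert rmse_large < rmse_small


class TestContrasts:
    def _fit(self, b_nohrt, b_hrt, cov=None):
        from exomir.twin_model import PoissonNormalFit

        cov = np.asarray(cov) if cov is not None else np.diag([0.01, 0.0625, 0.0625])
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(cov))  # NaN for planted negative variances
        return PoissonNormalFit(
            mir_id="m", beta0=1.0, beta_nohrt=b_nohrt, beta_hrt=b_hrt,
            sigma2=0.1, rho=0.5, loglik=-10.0, converged=True, n_quad=20,
            se=se, cov=cov,
        )

    def test_equal_betas_give_null_contrast(self):
        ct = wald_contrasts(self._fit(0.5, 0.5))
        row = ct[ct["comparison"] == "HRT_vs_NOHRT"].iloc[0]
        assert row["estimate"] == 0.0 and row["p"] == 1.0

    def test_wald_z2_pvalue(self):
        # estimate 0.5, se 0.25 -> z = 2, p ~ 0.0455
        ct = wald_contrasts(self._fit(0.5, 0.0))
        row = ct[ct["comparison"] == "NOHRT_vs_PRE"].iloc[0]
        assert row["se"] == pytest.approx(0.25)
        assert row["p"] == pytest.approx(2 * norm.sf(2.0), rel=1e-6)
        assert row["p"] == pytest.approx(0.0455, abs=1e-4)

    def test_nonfinite_se_gives_missing_p(self):
        cov = np.diag([0.01, -1.0, 0.0625])  # negative variance -> NaN SE
        ct = wald_contrasts(self._fit(0.4, 0.2, cov))
        assert np.isnan(ct.loc[ct["comparison"] == "NOHRT_vs_PRE", "p"].iloc[0])


class TestLikelihoodRatio:
    def test_lrt_agrees_with_wald_on_clear_effect(self):
        from exomir.twin_model import lrt_contrasts

        d = StudyDesign(n_singletons=8, n_pairs=10, n_mirs=1)
        p = SimulationParams([np.log(400)], beta_hrt=np.log(2), sigma2=0.1, rho=0.5, seed=3)
        cm, st_ = simulate_counts(d, p)
        cfg = ModelConfig()
        fit = fit_mir(cm.counts.iloc[0], st_, cfg, mir_id="m")
        wald = wald_contrasts(fit).set_index("comparison")["p"]
        lrt = lrt_contrasts(cm.counts.iloc[0], st_, fit, cfg).set_index("comparison")["p"]
        # both call the planted twin contrast and agree on the null one
        assert lrt["HRT_vs_NOHRT"] < 0.01 and wald["HRT_vs_NOHRT"] < 0.01
        assert lrt["NOHRT_vs_PRE"] == pytest.approx(wald["NOHRT_vs_PRE"], abs=0.05)
        # same estimates either way; only p differs
        pd.testing.assert_series_equal(
            wald_contrasts(fit)["estimate"],
            lrt_contrasts(cm.counts.iloc[0], st_, fit, cfg)["estimate"],
        )


class TestFdrAdjust:
    def test_hand_stepup_example(self):
        q = fdr_adjust([0.001, 0.01, 0.02, 0.8])
        np.testing.assert_allclose(q, [0.004, 0.02, 0.0266667, 0.8], atol=1e-6)

    def test_all_equal_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_nan_passthrough_and_domain(self):
        q = fdr_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and np.isfinite(q[0])
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_naive_oracle(self, pvals):
        np.testing.assert_allclose(fdr_adjust(pvals), bh_oracle(pvals), atol=1e-12)


class TestRunDeAnalysis:
    def test_single_mir_contrast_table(self, tiny_samples):
        d = StudyDesign(n_singletons=3, n_pairs=3, n_mirs=1)
        cm, st_ = simulate_counts(d, SimulationParams([np.log(60)], sigma2=0.1, rho=0.3, seed=5))
        fits, table = run_de_analysis(cm, st_)
        assert len(table) == 3
        np.testing.assert_allclose(table["q"], table["p"])  # single test per family

    def test_null_simulation_controls_false_calls(self):
        d = StudyDesign(n_singletons=8, n_pairs=10, n_mirs=40)
        params = SimulationParams(
            np.full(40, np.log(300)), sigma2=0.1, rho=0.5, seed=13
        )
        cm, st_ = simulate_counts(d, params)
        _, table = run_de_analysis(cm, st_)
        assert table["q"].ge(table["p"]).all()
        # BH at q<0.05 on null data: false-call proportion at most ~5%
        frac = (table["q"] < 0.05).mean()
        assert frac <= 0.05

    def test_requires_two_groups(self, study_dataset):
        from exomir import SampleTable

        counts, samples, _ = study_dataset
        pre_only = samples.table[samples.table["group"] == "PRE"]
        st_ = SampleTable(pre_only)
        with pytest.raises(ValueError):
            run_de_analysis(counts.subset(sample_ids=st_.sample_ids), st_)

    def test_reported_group_means_are_rounded_arithmetic_means(self, tiny_samples):
        d = StudyDesign(n_singletons=3, n_pairs=3, n_mirs=2)
        cm, st_ = simulate_counts(d, SimulationParams(np.full(2, np.log(90)), seed=6))
        _, table = run_de_analysis(cm, st_)
        mir = table["mir_id"].iloc[0]
        expected = np.rint(cm.counts.loc[mir, st_.group_samples("PRE")].mean())
        assert table.loc[table["mir_id"] == mir, "mean_PRE"].iloc[0] == expected
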