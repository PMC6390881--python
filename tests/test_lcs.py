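"""Latent change score models: recovery, constraints and fit indices."""

import numpy as np
import pandas as pd
import pytest

from metacog.lcs import (
    Constraints,
    chisq_diff,
    fit_bivariate_lcs,
    fit_univariate_lcs,
)


def make_bivariate(
    rng,
    n=500,
    alphas=(0.3, 0.2),
    betas=(-0.6, -0.5),
    gammas=(-0.3, 0.0),
    resid_sd=0.08,
    pre_mean=(0.6, 0.55),
    pre_cov=((0.02, 0.008), (0.008, 0.015)),
):
    """Synthetic two-group data from the bivariate change equations."""
    frames = []
    for g in ("control", "experimental"):
        pre = rng.multivariate_normal(pre_mean, pre_cov, size=n)
        P1, M1 = pre.T
        dP = alphas[0] + betas[0] * P1 + gammas[0] * M1 + rng.normal(0, resid_sd, n)
        dM = alphas[1] + betas[1] * M1 + gammas[1] * P1 + rng.normal(0, resid_sd, n)
        frames.append(
            pd.DataFrame(
                dict(group=g, P_pre=P1, P_post=P1 + dP, M_pre=M1, M_post=M1 + dM)
            )
        )
    return pd.concat(frames, ignore_index=True)


def make_univariate(rng, n=500, alpha=0.8, beta=-0.5, resid_sd=0.1):
    frames = []
    for g in ("control", "experimental"):
        pre = rng.normal(0.6, 0.15, n)
        d = alpha + beta * pre + rng.normal(0, resid_sd, n)
        frames.append(pd.DataFrame(dict(group=g, P_pre=pre, P_post=pre + d)))
    return pd.concat(frames, ignore_index=True)


class TestUnivariate:
    def test_null_model_recovery(self):
        data = make_univariate(np.random.default_rng(0), alpha=0.0, beta=0.0)
        fit = fit_univariate_lcs(data, "P", Constraints())
        for g in ("control", "experimental"):
            assert abs(fit.params[("alpha", g)]) < 2 * fit.se[("alpha", g)] + 1e-3
            assert abs(fit.params[("beta", g)]) < 2 * fit.se[("beta", g)] + 1e-3

    def test_parameter_recovery_within_2se(self):
        data = make_univariate(np.random.default_rng(0), alpha=0.8, beta=-0.5)
        fit = fit_univariate_lcs(data, "P", Constraints())
        for g in ("control", "experimental"):
            assert abs(fit.params[("alpha", g)] - 0.8) < 2 * fit.se[("alpha", g)]
            assert abs(fit.params[("beta", g)] + 0.5) < 2 * fit.se[("beta", g)]

    def test_saturated_chi_square_zero(self, rng):
        data = make_univariate(rng, n=120)
        fit = fit_univariate_lcs(data, "P", Constraints())
        assert fit.df == 0
        assert fit.chi_square == pytest.approx(0.0, abs=1e-4)

    def test_default_constraints_give_df_two(self, rng):
        data = make_univariate(rng, n=120)
        fit = fit_univariate_lcs(data, "P")
        assert fit.df == 2


class TestBivariate:
    def test_decoupled_gammas_near_zero(self, rng):
        data = make_bivariate(rng, gammas=(0.0, 0.0))
        fit = fit_bivariate_lcs(data, Constraints())
        for g in ("control", "experimental"):
            for name in ("gamma_P", "gamma_M"):
                assert abs(fit.params[(name, g)]) < 2 * fit.se[(name, g)] + 1e-3

    def test_parameter_recovery_within_2se(self, rng):
        truth = dict(
            alpha_P=0.3, alpha_M=0.2, beta_P=-0.6, beta_M=-0.5, gamma_P=-0.3, gamma_M=0.0
        )
        data = make_bivariate(rng, n=1000)
        fit = fit_bivariate_lcs(data, Constraints())
        for g in ("control", "experimental"):
            for name, val in truth.items():
                assert abs(fit.params[(name, g)] - val) < 2 * fit.se[(name, g)] + 1e-3

    def test_saturated_moment_matching(self, rng):
        """Model-implied moments at the MLE reproduce the sample moments
        of a saturated specification."""
        from metacog.lcs import _implied_bivariate, _suff_stats, BIVARIATE_PARAMS

        data = make_bivariate(rng, n=300)
        fit = fit_bivariate_lcs(data, Constraints())
        cols = ("P_pre", "P_post", "M_pre", "M_post")
        for g, (n, ybar, S) in zip(
            ("control", "experimental"), _suff_stats(data, cols)
        ):
            p = {name: fit.params[(name, g)] for name in BIVARIATE_PARAMS}
            mu, Sig = _implied_bivariate(p)
            assert np.allclose(mu, ybar, atol=1e-4)
            assert np.allclose(Sig, S, atol=1e-4)

    def test_change_score_identity(self, rng):
        """With the pre->post loading fixed at 1, the latent change equals
        the observed difference: the saturated MLE matches per-group OLS of
        (post - pre) on the pre scores."""
        data = make_bivariate(rng, n=400)
        fit = fit_bivariate_lcs(data, Constraints())
        for g in ("control", "experimental"):
            sub = data[data.group == g]
            X = np.column_stack([np.ones(len(sub)), sub.P_pre, sub.M_pre])
            coef, *_ = np.linalg.lstsq(X, sub.P_post - sub.P_pre, rcond=None)
            assert fit.params[("alpha_P", g)] == pytest.approx(coef[0], abs=1e-3)
            assert fit.params[("beta_P", g)] == pytest.approx(coef[1], abs=1e-3)
            assert fit.params[("gamma_P", g)] == pytest.approx(coef[2], abs=1e-3)

    def test_estimates_invariant_to_row_order(self, rng):
        data = make_bivariate(rng, n=150)
        fit1 = fit_bivariate_lcs(data)
        fit2 = fit_bivariate_lcs(data.sample(frac=1.0, random_state=1))
        for k, v in fit1.params.items():
            assert fit2.params[k] == pytest.approx(v, abs=1e-5)


class TestFitStatistics:
    def test_perfect_fit_index_endpoints(self, rng):
        data = make_bivariate(rng, n=200)
        fit = fit_bivariate_lcs(data, Constraints())
        assert fit.rmsea == 0.0
        assert fit.cfi == 1.0
        assert fit.srmr == pytest.approx(0.0, abs=1e-3)

    def test_free_model_likelihood_dominates_constrained(self, rng):
        data = make_bivariate(rng, n=200)
        free = fit_bivariate_lcs(data, Constraints())
        constrained = fit_bivariate_lcs(data)
        assert free.log_likelihood >= constrained.log_likelihood - 1e-6

    def test_chisq_diff_of_identical_models_is_zero(self, rng):
        data = make_bivariate(rng, n=200)
        free = fit_bivariate_lcs(data, Constraints())
        free2 = fit_bivariate_lcs(data, Constraints.of("mu_P_pre"))
        dchi, ddf, p = chisq_diff(free2, free)
        assert ddf == 1
        assert dchi >= -1e-6

    def test_chisq_diff_rejects_non_nested_direction(self, rng):
        data = make_bivariate(rng, n=200)
        free = fit_bivariate_lcs(data, Constraints())
        restricted = fit_bivariate_lcs(data)
        with pytest.raises(ValueError):
            chisq_diff(free, restricted)

    def test_group_difference_detected_by_lr_test(self, rng):
        """Strongly group-different self-feedback is flagged by the
        chi-square difference test at large n."""
        frames = []
        for g, beta in (("control", -0.2), ("experimental", -0.8)):
            pre = rng.normal(0.6, 0.15, 500)
            d = 0.3 + beta * pre + rng.normal(0, 0.08, 500)
            frames.append(pd.DataFrame(dict(group=g, P_pre=pre, P_post=pre + d)))
        data = pd.concat(frames, ignore_index=True)
        free = fit_univariate_lcs(data, "P", Constraints())
        restricted = fit_univariate_lcs(
            data, "P", Constraints.of("mu_pre", "var_pre", "alpha", "beta", "var_e")
        )
        dchi, ddf, p = chisq_diff(restricted, free)
        assert p < 1e-6

    def test_misspecification_rmsea_tracks_noncentrality(self, rng):
        """Population RMSEA from a huge-sample fit of a misspecified model
        falls inside the 90% RMSEA CI of a moderate-sample fit of the same
        model (noncentral chi-square oracle)."""
        def gen(n, seed):
            r = np.random.default_rng(seed)
            frames = []
            for g, beta in (("control", -0.25), ("experimental", -0.75)):
                pre = r.normal(0.6, 0.15, n)
                d = 0.3 + beta * pre + r.normal(0, 0.1, n)
                frames.append(pd.DataFrame(dict(group=g, P_pre=pre, P_post=pre + d)))
            return pd.concat(frames, ignore_index=True)

        constraints = Constraints.of("mu_pre", "var_pre", "alpha", "beta", "var_e")
        big = fit_univariate_lcs(gen(40000, 1), "P", constraints)
        pop_rmsea = np.sqrt(2 * big.chi_square / (big.df * (sum(big.n_obs) - 1)))
        small = fit_univariate_lcs(gen(150, 2), "P", constraints)
        lo, hi = small.rmsea_ci
        assert lo <= pop_rmsea <= hi


class TestValidation:
    def test_missing_values_rejected(self, rng):
        data = make_bivariate(rng, n=50)
        data.loc[0, "P_post"] = np.nan
        with pytest.raises(ValueError):
            fit_bivariate_lcs(data)

    def test_small_groups_rejected(self, rng):
        data = make_bivariate(rng, n=5)
        with pytest.raises(ValueError):
            fit_bivariate_lcs(data)
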