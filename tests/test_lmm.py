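"""Crossed-random-intercepts mixed model: REML correctness against
independent oracles, contrast algebra, standardization and invariances."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from dyadisc import CrossedLMM, corrected_df, fit_continuous_model
from dyadisc.errors import (
    DegenerateCovariateError,
    InsufficientDataError,
    SingularDesignError,
    ValidationError,
)
from dyadisc.lmm import standardize_variables

from conftest import (
    doubled_with_response,
    make_group_design,
    simulate_dyadic_response,
)


class TestCorrectedDf:
    def test_arithmetic(self):
        assert corrected_df(2144, 4) == 2140
        assert corrected_df(1952, 10) == 1942

    def test_boundary_raises(self):
        with pytest.raises(InsufficientDataError):
            corrected_df(10, 10)


class TestStandardize:
    def test_simple_column(self):
        np.testing.assert_allclose(standardize_variables([1.0, 2.0, 3.0]),
                                   [-1, 0, 1])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        x = standardize_variables(rng.normal(size=30))
        np.testing.assert_allclose(standardize_variables(x), x, atol=1e-12)

    def test_doubling_commutes_with_unique_mask(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        doubled = np.concatenate([x, x])
        mask = np.concatenate([np.ones(20, bool), np.zeros(20, bool)])
        np.testing.assert_allclose(
            standardize_variables(doubled, mask)[:20],
            standardize_variables(x),
        )

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateCovariateError):
            standardize_variables(np.ones(10))


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(12)
    dyads, _, _ = make_group_design(16, rng)
    y = simulate_dyadic_response(
        dyads, {"NN": 0.0, "NL": -0.3, "LL": -0.6}, 0.2, 0.8, rng)
    doubled, ydd = doubled_with_response(dyads, y)
    return CrossedLMM().fit(doubled, ydd), doubled, ydd


class TestFitBasics:
    def test_fitted_attributes(self, fitted):
        m, doubled, _ = fitted
        assert m.k_ == len(m.beta_) == 3
        assert m.n_unique_ == len(doubled) // 2
        assert m.df_ == m.n_unique_ - 3
        assert min(m.var_participant1_, m.var_participant2_,
                   m.var_resid_) >= 0
        assert m.converged_

    def test_zero_response_gives_zero_fit(self, fitted):
        _, doubled, _ = fitted
        m = CrossedLMM(standardize=False).fit(doubled, np.zeros(len(doubled)))
        assert np.allclose(m.beta_, 0)
        assert m.var_participant1_ == m.var_participant2_ == m.var_resid_ == 0

    def test_sklearn_params_round_trip(self):
        m = CrossedLMM(alternative="less")
        assert CrossedLMM(**m.get_params()).alternative == "less"

    def test_singular_design_names_aliased_column(self, fitted):
        _, doubled, ydd = fitted
        bad = doubled.copy()
        bad["dup"] = (bad["group"] == "LL").astype(float)  # aliases a dummy
        with pytest.raises(SingularDesignError):
            CrossedLMM(covariates=("dup",)).fit(bad, ydd)

    def test_mismatched_lengths_rejected(self, fitted):
        _, doubled, ydd = fitted
        with pytest.raises(ValidationError):
            CrossedLMM().fit(doubled, ydd[:-1])


class TestOracles:
    def test_gls_at_null_components_equals_ols(self):
        """With variance components fixed at zero the fit is exactly OLS on
        the unique dyads."""
        rng = np.random.default_rng(3)
        dyads, _, _ = make_group_design(20, rng)
        y = simulate_dyadic_response(
            dyads, {"NN": 0.0, "NL": -0.25, "LL": -0.5}, 0.0, 1.0, rng)
        doubled, ydd = doubled_with_response(dyads, y)
        m = CrossedLMM(var_ratios=(0.0, 0.0)).fit(doubled, ydd)
        X = np.column_stack([
            np.ones(len(dyads)),
            (dyads["group"] == "LL").to_numpy(float),
            (dyads["group"] == "NL").to_numpy(float),
        ])
        yz = (y - y.mean()) / y.std(ddof=1)
        beta_ols = np.linalg.lstsq(X, yz, rcond=None)[0]
        np.testing.assert_allclose(m.beta_.to_numpy(), beta_ols, atol=1e-10)

    def test_matches_statsmodels_crossed_reml(self):
        """Betas, variance components, SEs and the REML log-likelihood agree
        with statsmodels MixedLM fitting the same crossed structure."""
        rng = np.random.default_rng(7)
        dyads, _, _ = make_group_design(12, rng)
        y = simulate_dyadic_response(
            dyads, {"NN": 0.0, "NL": -0.3, "LL": -0.6}, 0.25, 1.0, rng)
        doubled, ydd = doubled_with_response(dyads, y)
        m = CrossedLMM(standardize=False, redundancy_correction=False).fit(
            doubled, ydd)
        data = doubled.copy()
        data["y"] = ydd
        data["g"] = 1
        sm_fit = smf.mixedlm(
            'y ~ C(group, Treatment("NN"))', data, groups="g",
            vc_formula={"p1": "0 + C(participant_1)",
                        "p2": "0 + C(participant_2)"},
        ).fit(reml=True, method="lbfgs")
        np.testing.assert_allclose(m.beta_.to_numpy(),
                                   sm_fit.fe_params.to_numpy(), atol=1e-4)
        np.testing.assert_allclose(
            [m.var_participant1_, m.var_participant2_],
            sm_fit.vcomp, atol=1e-4)
        assert m.var_resid_ == pytest.approx(sm_fit.scale, abs=1e-4)
        assert m.reml_loglik_ == pytest.approx(sm_fit.llf, abs=1e-4)
        np.testing.assert_allclose(
            np.sqrt(np.diag(m.vcov_)), sm_fit.bse_fe.to_numpy(), atol=1e-4)

    def test_noiseless_group_means_recovered_exactly(self):
        rng = np.random.default_rng(5)
        dyads, _, _ = make_group_design(10, rng)
        means = {"LL": -1.0, "NL": 0.0, "NN": 1.0}
        y = dyads["group"].map(means).to_numpy(float)
        doubled, ydd = doubled_with_response(dyads, y)
        m = CrossedLMM(standardize=False, var_ratios=(0.0, 0.0)).fit(
            doubled, ydd)
        c = m.contrasts().set_index("contrast")["estimate"]
        assert c["LL_vs_NN"] == pytest.approx(-2.0, abs=1e-10)
        assert c["LL_vs_NL"] == pytest.approx(-1.0, abs=1e-10)


class TestContrasts:
    def test_linear_identity(self, fitted):
        m, _, _ = fitted
        c = m.contrasts().set_index("contrast")["estimate"]
        assert c["LL_vs_NN"] == pytest.approx(c["LL_vs_NL"] + c["NL_vs_NN"],
                                              abs=1e-12)

    def test_se_equals_bruteforce_quadratic_form(self, fitted):
        m, _, _ = fitted
        out = m.contrasts().set_index("contrast")
        vec = {"Intercept": 0.0, "group[LL]": 1.0, "group[NL]": -1.0}
        c = np.array([vec[n] for n in m.beta_names_])
        se = np.sqrt(c @ m.vcov_.to_numpy() @ c)
        assert out.at["LL_vs_NL", "se"] == pytest.approx(se, abs=1e-12)

    def test_t_df_and_sign_fields(self, fitted):
        m, _, _ = fitted
        out = m.contrasts()
        np.testing.assert_allclose(out["t"], out["estimate"] / out["se"])
        assert (out["df"] == m.n_unique_ - m.k_).all()
        assert (out["direction"] == np.sign(out["estimate"])).all()

    def test_one_sided_option(self, fitted):
        m, doubled, ydd = fitted
        less = CrossedLMM(alternative="less").fit(doubled, ydd).contrasts()
        two = m.contrasts()
        for i in range(3):
            t = two.loc[i, "t"]
            expected = (two.loc[i, "p"] / 2 if t < 0
                        else 1 - two.loc[i, "p"] / 2)
            assert less.loc[i, "p"] == pytest.approx(expected)


class TestContinuousModel:
    def test_slope_recovered(self):
        rng = np.random.default_rng(11)
        dyads, _, _ = make_group_design(24, rng)
        x = standardize_variables(dyads["max_loneliness"].to_numpy())
        dyads = dyads.assign(max_loneliness=x)  # predictor on unit scale
        y = -0.5 * x + rng.normal(0, 0.5, len(dyads))
        doubled, ydd = doubled_with_response(dyads, y)
        fit, test = fit_continuous_model(doubled, ydd, standardize=False)
        assert test.at[0, "contrast"] == "max_loneliness_slope"
        assert test.at[0, "estimate"] == pytest.approx(-0.5, abs=0.1)
        assert test.at[0, "p"] < 1e-6 and test.at[0, "direction"] == -1

    def test_constant_trait_rejected(self):
        rng = np.random.default_rng(2)
        dyads, _, _ = make_group_design(10, rng)
        dyads["max_loneliness"] = 17.0
        doubled, ydd = doubled_with_response(dyads,
                                             rng.normal(size=len(dyads)))
        with pytest.raises(DegenerateCovariateError):
            fit_continuous_model(doubled, ydd)


class TestInvariances:
    def test_label_swap_leaves_fixed_effects(self, fitted):
        m, doubled, ydd = fitted
        swapped = doubled.copy()
        swapped[["participant_1", "participant_2"]] = doubled[
            ["participant_2", "participant_1"]].to_numpy()
        m2 = CrossedLMM().fit(swapped, ydd)
        np.testing.assert_allclose(m.beta_.to_numpy(), m2.beta_.to_numpy(),
                                   atol=1e-10)

    def test_role_variances_nearly_equal_on_symmetric_data(self):
        rng = np.random.default_rng(17)
        diffs = []
        for _ in range(10):
            dyads, _, _ = make_group_design(20, rng)
            y = simulate_dyadic_response(
                dyads, {"NN": 0.0, "NL": -0.2, "LL": -0.4}, 0.3, 0.7, rng)
            doubled, ydd = doubled_with_response(dyads, y)
            m = CrossedLMM().fit(doubled, ydd)
            v1, v2 = m.var_participant1_, m.var_participant2_
            if max(v1, v2) > 1e-8:
                diffs.append(abs(v1 - v2) / max(v1, v2))
        assert np.mean(diffs) < 0.10

    def test_reml_criterion_no_worse_than_null_components(self, fitted):
        m, doubled, ydd = fitted
        null = CrossedLMM(var_ratios=(0.0, 0.0)).fit(doubled, ydd)
        assert m.reml_loglik_ >= null.reml_loglik_ - 1e-8
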