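"""Likelihood, age curve, priors and the marginalized posterior."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bevpool import (
    BeverageModel,
    ModelConfig,
    ModelParams,
    ParameterSpace,
    RegionHierarchy,
    SurveyStratum,
    ValidationError,
    age_curve,
    integrate_age,
    log_transform_obs,
    standardize_availability,
)
from bevpool.exposure_model import (
    DEFAULT_KNOTS,
    ObservationLikelihoodInput,
    availability_z_lookup,
)


def _hierarchy():
    return RegionHierarchy(
        pd.DataFrame(
            {
                "country_id": ["AAA", "BBB", "CCC"],
                "region_id": ["R1", "R1", "R2"],
                "super_region_id": ["S1", "S1", "S2"],
            }
        )
    )


def _obs(y=0.0, se=1.0, country="AAA", sex="female", year=2000, age_lo=20, age_hi=21,
         z=0.0, **flags):
    defaults = dict(subnational=False, household=False, secondary=False,
                    suboptimal=False)
    defaults.update(flags)
    return ObservationLikelihoodInput(
        y=y, se_y=se, age_lo=age_lo, age_hi=age_hi, sex=sex, country_id=country,
        year=year, z_avail=z, **defaults
    )


def _params(space, **kw):
    p = space.blank_params()
    for k, v in kw.items():
        setattr(p, k, v)
    return p


class TestLogTransform:
    def test_unit_mean_hits_se_floor(self):
        s = SurveyStratum("AAA", 2000, "female", 20, 40, 1.0, 0.0, 10)
        o = log_transform_obs(s)
        assert o.y == 0.0
        assert o.se_y == 0.01

    def test_delta_method_arithmetic(self):
        m = math.e
        s = SurveyStratum("AAA", 2000, "female", 20, 40, m, math.sqrt(10) * m, 10)
        o = log_transform_obs(s)
        assert o.y == pytest.approx(1.0)
        assert o.se_y == pytest.approx(1.0)

    def test_zero_mean_floored_and_flagged(self):
        s = SurveyStratum("AAA", 2000, "female", 20, 40, 0.0, 0.1, 50)
        o = log_transform_obs(s)
        assert o.floored
        assert o.y == pytest.approx(math.log(0.005))

    def test_flags_are_non_preferred_indicators(self):
        s = SurveyStratum("AAA", 2000, "female", 20, 40, 1.0, 0.5, 50,
                          nationally_representative=False, individual_level=True,
                          primary_metric=False, optimal_assessment=True)
        o = log_transform_obs(s)
        np.testing.assert_array_equal(o.flags, [1.0, 0.0, 1.0, 0.0])


class TestAgeCurve:
    def test_zero_coefficients_vanish_everywhere(self):
        gamma = np.zeros(len(DEFAULT_KNOTS))
        for age in (20, 35.5, 47, 80, 100):
            assert age_curve(gamma, age) == 0.0

    def test_linear_interpolation_between_knots(self):
        gamma = np.zeros(len(DEFAULT_KNOTS))
        gamma[1] = 1.0  # knot at 30
        assert age_curve(gamma, 25) == pytest.approx(0.5)

    def test_matches_numpy_interp_oracle(self):
        rng = np.random.default_rng(1)
        gamma = rng.normal(0, 1, len(DEFAULT_KNOTS))
        gamma[0] = 0.0
        for age in (47, 23.2, 88.5):
            expected = np.interp(age, DEFAULT_KNOTS, gamma)
            assert age_curve(gamma, age) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_age_rejected(self):
        with pytest.raises(ValidationError):
            age_curve(np.zeros(len(DEFAULT_KNOTS)), 19)


class TestIntegrateAge:
    def test_constant_curve_integrates_to_itself(self):
        gamma = np.full(len(DEFAULT_KNOTS), 0.0)
        gamma[:] = 0.7  # constant curve (first knot nonzero is fine here)
        assert integrate_age(gamma, 20, 40) == pytest.approx(0.7)

    def test_linear_curve_uniform_weights_hits_midpoint(self):
        gamma = np.asarray(DEFAULT_KNOTS) - 20.0  # slope 1 in age
        # integer ages 20..39 average to 29.5
        assert integrate_age(gamma, 20, 40) == pytest.approx(9.5)

    def test_skewed_weights_match_direct_sum_oracle(self):
        rng = np.random.default_rng(2)
        gamma = rng.normal(0, 0.5, len(DEFAULT_KNOTS))
        gamma[0] = 0.0
        weights = {a: float(rng.uniform(10, 1000)) for a in range(40, 60)}
        expected = sum(
            weights[a] * age_curve(gamma, a) for a in range(40, 60)
        ) / sum(weights.values())
        assert integrate_age(gamma, 40, 60, weights) == pytest.approx(expected, abs=1e-12)

    def test_zero_weight_slice_rejected(self):
        with pytest.raises(ValidationError):
            integrate_age(np.zeros(len(DEFAULT_KNOTS)), 40, 60, {a: 0.0 for a in range(40, 60)})


class TestLinearPredictor:
    def test_all_zero_params_predict_zero(self):
        model = BeverageModel([_obs()], _hierarchy())
        assert model.linear_predictor(_params(model.space), _obs()) == 0.0

    def test_intercept_only(self):
        model = BeverageModel([_obs()], _hierarchy())
        assert model.linear_predictor(_params(model.space, beta0=1.0), _obs()) == 1.0

    def test_identifiability_anchor(self):
        # preferred flags, female, year 2000, z = 0, age 20 -> exactly beta0
        model = BeverageModel([_obs()], _hierarchy())
        rng = np.random.default_rng(0)
        gamma = rng.normal(0, 1, len(DEFAULT_KNOTS))
        gamma[0] = 0.0
        p = _params(model.space, beta0=-0.4, gamma_age=gamma, delta_sex=0.3,
                    phi_t=0.2, lambda_avail=0.5, b_house=-0.2)
        assert model.linear_predictor(p, _obs(age_lo=20, age_hi=21)) == pytest.approx(-0.4)

    def test_full_toy_vector_matches_hand_sum(self):
        model = BeverageModel([_obs()], _hierarchy())
        sp = model.space
        gamma = np.zeros(len(DEFAULT_KNOTS))
        gamma[1] = 0.5  # age 30 knot
        p = _params(
            sp, beta0=1.0, gamma_age=gamma, delta_sex=0.25, phi_t=0.3,
            lambda_avail=0.4, b_sub=0.1, b_house=-0.2,
            u_s=np.array([0.05, 0.0]), u_r=np.array([0.07, 0.0]),
            u_c=np.array([0.09, 0.0, 0.0]),
        )
        obs = _obs(country="AAA", sex="male", year=2010, age_lo=25, age_hi=26,
                   z=2.0, subnational=True, household=True)
        expected = (
            1.0          # beta0
            + 0.25       # age 25 -> halfway to the age-30 knot coefficient 0.5
            + 0.25       # male offset
            + 0.3 * 1.0  # one decade after 2000
            + 0.4 * 2.0  # availability
            + 0.05 + 0.07 + 0.09  # AAA's nested intercepts
            + 0.1 - 0.2  # subnational + household offsets
        )
        assert model.linear_predictor(p, obs) == pytest.approx(expected, abs=1e-12)

    def test_unknown_country_rejected(self):
        model = BeverageModel([_obs()], _hierarchy())
        with pytest.raises(ValidationError):
            model.linear_predictor(_params(model.space), _obs(country="ZZZ"))


class TestLikelihoodAndPriors:
    def test_standard_normal_peak(self):
        # v = se^2 + sigma_eps^2 = 0.8^2 + 0.6^2 = 1 at mu = y
        model = BeverageModel([_obs(y=0.3, se=0.8)], _hierarchy())
        p = _params(model.space, beta0=0.3, sigma_eps=0.6)
        for name in ("sigma_add_sub", "sigma_add_house", "sigma_add_secondary",
                     "sigma_add_subopt"):
            setattr(p, name, 1e-9)
        assert model.log_likelihood(p) == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_duplicated_observation_doubles_contribution(self):
        one = BeverageModel([_obs(y=0.5)], _hierarchy())
        two = BeverageModel([_obs(y=0.5), _obs(y=0.5)], _hierarchy())
        p1 = _params(one.space, beta0=0.1)
        p2 = _params(two.space, beta0=0.1)
        assert two.log_likelihood(p2) == pytest.approx(2 * one.log_likelihood(p1))

    def test_five_obs_toy_matches_scipy_normal_sum(self):
        rng = np.random.default_rng(4)
        obs = [
            _obs(y=float(rng.normal()), se=float(rng.uniform(0.1, 1.0)),
                 country=c, subnational=bool(f))
            for c, f in zip(["AAA", "BBB", "CCC", "AAA", "BBB"], [0, 1, 0, 1, 0])
        ]
        model = BeverageModel(obs, _hierarchy())
        p = _params(model.space, beta0=0.2, sigma_eps=0.15, sigma_add_sub=0.3)
        expected = 0.0
        for o in obs:
            v = o.se_y**2 + p.sigma_eps**2
            v += p.sigma_add_sub**2 * o.subnational
            v += (p.sigma_add_house**2 * o.household
                  + p.sigma_add_secondary**2 * o.secondary
                  + p.sigma_add_subopt**2 * o.suboptimal)
            mu = model.linear_predictor(p, o)
            expected += stats.norm.logpdf(o.y, mu, np.sqrt(v))
        assert model.log_likelihood(p) == pytest.approx(expected, abs=1e-9)

    def test_variance_inflation_never_raises_weight(self):
        model = BeverageModel([_obs(y=0.0)], _hierarchy())
        p = _params(model.space, sigma_add_house=0.4)
        ll_preferred = model.log_likelihood(p)
        model_flagged = BeverageModel([_obs(y=0.0, household=True)], _hierarchy())
        p2 = _params(model_flagged.space, sigma_add_house=0.4)
        assert model_flagged.log_likelihood(p2) < ll_preferred

    def test_prior_support_and_mode(self):
        model = BeverageModel([_obs()], _hierarchy())
        bad = _params(model.space)
        bad.sigma_eps = -1.0
        assert model.log_prior(bad) == -np.inf
        centered = _params(model.space)
        shifted = _params(model.space, u_c=np.array([0.5, 0.0, 0.0]))
        assert model.log_prior(centered) > model.log_prior(shifted)

    def test_prior_matches_term_by_term_density_oracle(self):
        model = BeverageModel([_obs()], _hierarchy())
        sp = model.space
        rng = np.random.default_rng(9)
        gamma = rng.normal(0, 0.3, len(DEFAULT_KNOTS))
        gamma[0] = 0.0
        p = _params(
            sp, beta0=0.3, gamma_age=gamma, delta_sex=0.1, phi_t=-0.2,
            lambda_avail=0.4, b_sub=0.05, b_house=-0.1, b_secondary=0.02,
            b_subopt=-0.03, u_s=rng.normal(0, 0.2, 2), u_r=rng.normal(0, 0.2, 2),
            u_c=rng.normal(0, 0.2, 3), tau_s=0.3, tau_r=0.25, tau_c=0.2,
            sigma_eps=0.12,
        )
        cfg = model.config
        expected = sum(
            stats.norm.logpdf(x, 0, cfg.fixed_effect_sd)
            for x in [p.beta0, p.delta_sex, p.phi_t, p.lambda_avail,
                      p.b_sub, p.b_house, p.b_secondary, p.b_subopt]
        )
        inc = np.diff(gamma)
        expected += stats.norm.logpdf(inc, 0, np.sqrt(sp.age_rw_var)).sum()
        expected += stats.norm.logpdf(p.u_s, 0, p.tau_s).sum()
        expected += stats.norm.logpdf(p.u_r, 0, p.tau_r).sum()
        expected += stats.norm.logpdf(p.u_c, 0, p.tau_c).sum()
        expected += stats.halfnorm.logpdf(p.sds, scale=cfg.sd_prior_scale).sum()
        assert model.log_prior(p) == pytest.approx(expected, abs=1e-9)

    def test_posterior_is_sum_of_components(self):
        model = BeverageModel([_obs(y=0.4)], _hierarchy())
        p = _params(model.space, beta0=0.2)
        assert model.log_posterior(p) == pytest.approx(
            model.log_prior(p) + model.log_likelihood(p)
        )
        bad = _params(model.space)
        bad.tau_c = -0.5
        assert model.log_posterior(bad) == -np.inf


class TestMarginalization:
    def test_marginal_equals_joint_minus_conditional_gaussian(self, tiny_world,
                                                              tiny_survey):
        strata, _ = tiny_survey
        av = standardize_availability(tiny_world.availability)
        z = availability_z_lookup(av)
        obs = [log_transform_obs(s, z[(s.country_id, s.year)]) for s in strata]
        model = BeverageModel(obs, tiny_world.hierarchy,
                              populations=tiny_world.populations)
        rng = np.random.default_rng(6)
        vec = model.marginal_init_vector() + 0.05 * rng.standard_normal(model.marginal_dim)
        pieces = model._marginal_pieces(vec)
        _, _, _, _, _, r, zd, m = pieces
        u_hat = np.linalg.solve(m, zd @ r)
        cov = np.linalg.inv(m)
        marginal = model.marginal_log_posterior(vec)
        for _ in range(3):
            u = u_hat + 0.3 * rng.standard_normal(len(u_hat))
            joint = model.packed_log_posterior(model.expand_marginal(vec, u))
            gauss = stats.multivariate_normal.logpdf(u, u_hat, cov)
            assert joint - marginal == pytest.approx(gauss, abs=1e-8)

    def test_conditional_draws_have_conditional_moments(self, tiny_world, tiny_survey):
        strata, _ = tiny_survey
        av = standardize_availability(tiny_world.availability)
        z = availability_z_lookup(av)
        obs = [log_transform_obs(s, z[(s.country_id, s.year)]) for s in strata]
        model = BeverageModel(obs, tiny_world.hierarchy)
        vec = model.marginal_init_vector()
        rng = np.random.default_rng(8)
        draws = np.stack([model.draw_random_effects(vec, rng) for _ in range(4000)])
        pieces = model._marginal_pieces(vec)
        _, _, _, _, _, r, zd, m = pieces
        u_hat = np.linalg.solve(m, zd @ r)
        cov = np.linalg.inv(m)
        mc_se = np.sqrt(np.diag(cov) / 4000)
        assert np.all(np.abs(draws.mean(axis=0) - u_hat) < 4 * mc_se)
        np.testing.assert_allclose(draws.var(axis=0), np.diag(cov), rtol=0.15)


class TestAvailability:
    def test_constant_series_rejected(self):
        df = pd.DataFrame({"country_id": ["A", "B"], "year": [2000, 2000],
                           "value": [3.0, 3.0]})
        with pytest.raises(ValidationError, match="zero variance"):
            standardize_availability(df)

    def test_two_point_series(self):
        df = pd.DataFrame({"country_id": ["A", "B"], "year": [2000, 2000],
                           "value": [0.0, 2.0]})
        out = standardize_availability(df)
        np.testing.assert_allclose(out["z_value"], [-1.0, 1.0])

    def test_matches_mean_sd_oracle_per_beverage(self):
        rng = np.random.default_rng(12)
        values = rng.uniform(5, 50, 8)
        df = pd.DataFrame({
            "country_id": list("ABCDEFGH"),
            "year": [2000] * 8,
            "beverage": ["ssb"] * 4 + ["milk"] * 4,
            "value": values,
        })
        out = standardize_availability(df)
        for bev in ("ssb", "milk"):
            sub = df[df["beverage"] == bev]["value"]
            expected = (sub - sub.mean()) / sub.std(ddof=0)
            np.testing.assert_allclose(
                out.loc[out["beverage"] == bev, "z_value"], expected
            )
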