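"""Generator properties: determinism, designed biases, recoverable truth."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from bevpool import (
    Cell,
    ValidationError,
    WorldConfig,
    corrected_sd,
    energy_standardize,
    make_world,
    person_means,
    simulate_recalls,
    simulate_surveys,
)


class TestMakeWorld:
    def test_same_seed_reproduces_world_bit_exactly(self, tiny_config):
        w1 = make_world(tiny_config)
        w2 = make_world(tiny_config)
        pd.testing.assert_frame_equal(w1.truth.surface, w2.truth.surface)
        pd.testing.assert_frame_equal(w1.availability, w2.availability)
        pd.testing.assert_frame_equal(w1.populations, w2.populations)

    def test_zero_variances_collapse_countries_onto_global_curve(self):
        # flat age curve too, so country-specific population weights inside
        # the age integration cannot introduce any spread of their own
        config = replace(
            WorldConfig(), tau_s=0.0, tau_r=0.0, tau_c=0.0, lambda_avail=0.0,
            gamma_age=(0.0,) * 8, seed=3,
        )
        world = make_world(config)
        surface = world.truth.surface
        spread = surface.groupby(["year", "sex", "age_lo"])["true_mean"].agg(
            lambda s: s.max() - s.min()
        )
        assert spread.max() < 1e-12

    def test_exposure_surface_equals_hand_built_predictor(self):
        config = replace(
            WorldConfig(), n_super_regions=1, n_regions=1, n_countries=2, seed=5
        )
        world = make_world(config)
        params = world.truth.params
        z = {(r.country_id, r.year): r.z_value
             for r in world.availability.itertuples(index=False)}
        row = world.truth.surface.iloc[0]
        space = world.space
        pop = world.populations
        mask = (
            (pop["country_id"] == row.country_id)
            & (pop["year"] == row.year)
            & (pop["sex"] == row.sex)
        )
        weights = dict(zip(pop.loc[mask, "age"], pop.loc[mask, "count"]))
        design = space.design_row(
            country_id=row.country_id, year=row.year, sex=row.sex,
            age_lo=row.age_lo, age_hi=row.age_hi,
            z_avail=z[(row.country_id, row.year)], pop_weights=weights,
        )
        theta = space.pack(params)[: space.n_linear]
        assert row.true_mean == pytest.approx(np.exp(design @ theta), rel=1e-12)

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            make_world(replace(WorldConfig(), survey_coverage=0.0))
        with pytest.raises(ValidationError):
            make_world(replace(WorldConfig(), n_countries=5, n_regions=4))


class TestSimulateSurveys:
    def test_zero_noise_preferred_flags_observe_truth_exactly(self):
        config = replace(
            WorldConfig(), sigma_eps=0.0, intake_cv=0.0,
            p_subnational=0.0, p_household=0.0, p_secondary=0.0, p_suboptimal=0.0,
            seed=9,
        )
        world = make_world(config)
        strata, _ = simulate_surveys(world)
        for s in strata[:20]:
            truth = world.truth.true_mean(
                Cell(s.country_id, s.year, s.sex, s.age_lo, s.age_hi)
            )
            assert s.mean_intake == pytest.approx(truth, rel=1e-9)

    def test_household_flag_shifts_by_designed_bias(self):
        config = replace(
            WorldConfig(), sigma_eps=0.0, intake_cv=0.0, sigma_add_house=0.0,
            p_subnational=0.0, p_household=1.0, p_secondary=0.0, p_suboptimal=0.0,
            seed=9,
        )
        world = make_world(config)
        strata, _ = simulate_surveys(world)
        for s in strata[:20]:
            truth = world.truth.true_mean(
                Cell(s.country_id, s.year, s.sex, s.age_lo, s.age_hi)
            )
            assert not s.individual_level
            assert s.mean_intake == pytest.approx(
                truth * np.exp(config.b_house), rel=1e-9
            )

    def test_stratum_count_is_combinatorial(self, default_world, default_survey):
        strata, covered = default_survey
        config = default_world.config
        expected = (
            len(covered) * len(config.years) * 2 * len(config.age_bands)
        )
        assert len(strata) == expected
        assert len(covered) == round(config.survey_coverage * config.n_countries)

    def test_same_seed_reproduces_strata(self, default_world):
        a, cov_a = simulate_surveys(default_world, seed=77)
        b, cov_b = simulate_surveys(default_world, seed=77)
        assert a == b and cov_a == cov_b


class TestSimulateAvailability:
    def test_every_country_year_present_exactly_once(self, default_world):
        counts = default_world.availability.groupby(["country_id", "year"]).size()
        assert (counts == 1).all()
        assert len(counts) == default_world.config.n_countries * len(
            default_world.config.years
        )

    def test_regression_recovers_generating_slope_and_intercept(self):
        config = replace(
            WorldConfig(), n_super_regions=2, n_regions=6, n_countries=60,
            years=(1990, 1995, 2000, 2005, 2010), avail_noise_sd=0.5, seed=21,
        )
        world = make_world(config)
        merged = world.availability.merge(
            world.truth.base_intake, on=["country_id", "year"]
        )
        slope, intercept = np.polyfit(merged["base_intake"], merged["value"], 1)
        assert slope == pytest.approx(config.avail_slope, rel=0.05)
        assert intercept == pytest.approx(config.avail_intercept, rel=0.10)


class TestIncomeAndBmiStandIns:
    def test_gni_table_is_classified_and_deterministic(self, default_world):
        from bevpool import simulate_gni

        a = simulate_gni(default_world, seed=1)
        b = simulate_gni(default_world, seed=1)
        pd.testing.assert_frame_equal(a, b)
        assert set(a["income_class"]) <= {"low", "lower_middle", "upper_middle", "high"}
        assert len(a) == default_world.config.n_countries

    def test_bmi_correlates_with_truth_at_configured_level(self):
        from bevpool import correlate_exposures, simulate_bmi

        config = replace(
            WorldConfig(), n_super_regions=2, n_regions=6, n_countries=120,
            bmi_intake_corr=0.6, seed=17,
        )
        world = make_world(config)
        bmi = simulate_bmi(world, seed=2)
        intake = world.truth.surface.rename(columns={"true_mean": "mean"})[
            ["country_id", "sex", "age_lo", "age_hi", "year", "mean"]
        ]
        out = correlate_exposures(
            intake[intake["year"] == 2010], bmi[bmi["year"] == 2010],
            by=("sex", "age_lo", "age_hi"),
        )
        # log-scale construction, natural-scale correlation: allow slack
        assert out["r"].mean() == pytest.approx(0.6, abs=0.12)


class TestSimulateRecalls:
    def test_zero_within_noise_recovers_between_sd(self, tiny_world):
        config = replace(tiny_world.config, within_sd=0.0)
        world = make_world(config)
        cell = Cell("CTY00", 1990, "female", 20, 50)
        records = simulate_recalls(world, cell, seed=2, n_persons=200)
        means = person_means(records)["mean_intake"]
        assert corrected_sd(records) == pytest.approx(
            float(np.std(means, ddof=1)), abs=1e-12
        )

    def test_moment_recovery_at_large_n(self, tiny_world):
        cell = Cell("CTY00", 1990, "female", 20, 50)
        records = simulate_recalls(tiny_world, cell, seed=3, n_persons=2000)
        config = tiny_world.config
        est_between = corrected_sd(records)
        # between SD within sampling error of the generating value
        assert est_between == pytest.approx(config.between_sd, rel=0.15)
        df = person_means(records)
        truth = tiny_world.truth.true_mean(cell)
        assert df["mean_intake"].mean() == pytest.approx(truth, abs=0.02)

    def test_uncorrelated_energy_makes_standardization_a_near_noop(self, tiny_world):
        config = replace(tiny_world.config, energy_intake_corr=0.0)
        world = make_world(config)
        cell = Cell("CTY00", 1990, "female", 20, 50)
        records = simulate_recalls(world, cell, seed=4, n_persons=1000)
        df = person_means(records)
        adjusted = energy_standardize(df["mean_intake"], df["mean_energy"], 2000.0)
        raw = df["mean_intake"].to_numpy()
        assert np.abs(adjusted - raw).max() < 0.05

    def test_day_count_validated(self, tiny_world):
        config = replace(tiny_world.config, recall_days=0)
        with pytest.raises(ValidationError):
            config.validate()
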