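"""Synthetic worlds with known ground truth for every pipeline stage.

A world is a strictly nested country/region/super-region hierarchy,
single-year-of-age population counts, a true exposure surface generated
from the same hierarchical model the package fits, partial-coverage
biased/noisy survey strata, a complete country-year availability series,
and optional per-person recall microdata.  Everything is a pure function
of ``(WorldConfig, seed)``.

The availability series tracks the *base* component of the truth (the
linear predictor without the availability term): availability values are
``a + b * (population-mean base intake) + noise``, standardized to z-scores,
and the final true log intake adds ``lambda_avail * z``.  The fitted model
is therefore exactly correctly specified, which is what makes interval-
coverage checks on synthetic worlds meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core_types import RegionHierarchy, SurveyStratum, ValidationError
from .exposure_model import (
    ModelConfig,
    ModelParams,
    ParameterSpace,
    standardize_availability,
)
from .posterior_summary import Cell
from .survey_prep import RecallRecord

__all__ = ["WorldConfig", "GroundTruth", "World", "make_world", "simulate_surveys",
           "simulate_availability", "simulate_recalls", "simulate_gni",
           "simulate_bmi"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WorldConfig:
    """Generating conditions for a synthetic world.

    Defaults describe a small SSB-like world: intake around 0.6
    servings/day globally, declining with age, higher in men, drifting up
    over time, with a several-fold spread across regions and 60% of
    countries holding any survey (availability is complete everywhere, as
    food-balance sheets are).
    """

    n_super_regions: int = 2
    n_regions: int = 4
    n_countries: int = 12
    years: tuple[int, ...] = (1990, 2010)
    age_bands: tuple[tuple[int, int], ...] = ((20, 40), (40, 60), (60, 100))
    seed: int = 0
    # true fixed effects (log-intake scale)
    beta0: float = -0.5
    gamma_age: tuple[float, ...] = (0.0, -0.08, -0.18, -0.30, -0.42, -0.55, -0.70, -0.90)
    delta_sex: float = 0.20
    phi_t: float = 0.15
    lambda_avail: float = 0.30
    # availability-generation: value = a + b * base intake + noise
    avail_intercept: float = 20.0
    avail_slope: float = 50.0
    avail_noise_sd: float = 4.0
    # true bias offsets and variance components
    b_sub: float = 0.10
    b_house: float = -0.15
    b_secondary: float = 0.10
    b_subopt: float = -0.10
    tau_s: float = 0.40
    tau_r: float = 0.25
    tau_c: float = 0.20
    sigma_eps: float = 0.10
    sigma_add_sub: float = 0.10
    sigma_add_house: float = 0.15
    sigma_add_secondary: float = 0.10
    sigma_add_subopt: float = 0.15
    # survey landscape
    survey_coverage: float = 0.6
    p_subnational: float = 0.25
    p_household: float = 0.20
    p_secondary: float = 0.20
    p_suboptimal: float = 0.25
    stratum_n: int = 200
    intake_cv: float = 0.8
    # recall microdata
    recall_days: int = 2
    recall_persons: int = 200
    between_sd: float = 0.10
    within_sd: float = 0.15
    energy_mean: float = 2000.0
    energy_sd: float = 350.0
    energy_intake_corr: float = 0.3
    # population counts per single year of age
    pop_min: int = 1000
    pop_max: int = 10000
    # income and BMI stand-in tables
    gni_log_min: float = np.log(600.0)
    gni_log_max: float = np.log(60_000.0)
    bmi_mean: float = 25.0
    bmi_sd: float = 2.0
    bmi_intake_corr: float = 0.5

    def validate(self) -> None:
        if not 0 < self.survey_coverage <= 1:
            raise ValidationError("survey_coverage must be in (0, 1]")
        if self.n_regions < self.n_super_regions or self.n_countries < self.n_regions:
            raise ValidationError("levels must nest: countries >= regions >= super-regions")
        if self.n_countries < 2 * self.n_regions:
            raise ValidationError("need >= 2 countries per region for recovery tests")
        if self.recall_days < 1:
            raise ValidationError("recall_days must be >= 1")
        for sd in (self.tau_s, self.tau_r, self.tau_c, self.sigma_eps,
                   self.between_sd, self.within_sd, self.avail_noise_sd):
            if sd < 0:
                raise ValidationError("SDs must be >= 0")


@dataclass
class GroundTruth:
    """True parameters and exposure surface of a synthetic world."""

    params: ModelParams
    surface: pd.DataFrame  # one row per cell with true_mean and base_log
    base_intake: pd.DataFrame  # (country_id, year) population-mean base intake
    seed: int

    def true_mean(self, cell: Cell) -> float:
        key = (cell.country_id, cell.year, cell.sex, cell.age_lo, cell.age_hi)
        return float(self._index[key])

    def __post_init__(self) -> None:
        self._index = {
            (r.country_id, r.year, r.sex, r.age_lo, r.age_hi): r.true_mean
            for r in self.surface.itertuples(index=False)
        }


@dataclass
class World:
    config: WorldConfig
    hierarchy: RegionHierarchy
    populations: pd.DataFrame
    availability: pd.DataFrame  # with z_value filled
    truth: GroundTruth
    space: ParameterSpace


def _code(prefix: str, i: int) -> str:
    return f"{prefix}{i:02d}"


def _build_hierarchy(config: WorldConfig) -> RegionHierarchy:
    rows = []
    for c in range(config.n_countries):
        r = c % config.n_regions
        s = r % config.n_super_regions
        rows.append(
            {
                "country_id": _code("CTY", c),
                "region_id": _code("REG", r),
                "super_region_id": _code("SUP", s),
            }
        )
    return RegionHierarchy(pd.DataFrame(rows))


def make_world(config: WorldConfig = WorldConfig(), model_config: ModelConfig = ModelConfig()) -> World:
    """Generate a complete world from the config's seed.

    Random effects are drawn N(0, tau^2) at each level; the true exposure
    per cell is exp(linear predictor) with the availability covariate
    built by :func:`simulate_availability` from the base surface.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_effects, rng_pop, rng_avail = (np.random.default_rng(s) for s in ss.spawn(3))

    hierarchy = _build_hierarchy(config)
    space = ParameterSpace(hierarchy, model_config)

    params = ModelParams(
        beta0=config.beta0,
        gamma_age=np.asarray(config.gamma_age, dtype=float),
        delta_sex=config.delta_sex,
        phi_t=config.phi_t,
        lambda_avail=config.lambda_avail,
        b_sub=config.b_sub,
        b_house=config.b_house,
        b_secondary=config.b_secondary,
        b_subopt=config.b_subopt,
        u_s=rng_effects.normal(0.0, config.tau_s, len(space.supers)) if config.tau_s > 0
        else np.zeros(len(space.supers)),
        u_r=rng_effects.normal(0.0, config.tau_r, len(space.regions)) if config.tau_r > 0
        else np.zeros(len(space.regions)),
        u_c=rng_effects.normal(0.0, config.tau_c, len(space.countries)) if config.tau_c > 0
        else np.zeros(len(space.countries)),
        # zero generating variances are floored so the truth vector stays
        # inside the model's parameter support
        tau_s=max(config.tau_s, 1e-12),
        tau_r=max(config.tau_r, 1e-12),
        tau_c=max(config.tau_c, 1e-12),
        sigma_add_sub=max(config.sigma_add_sub, 1e-12),
        sigma_add_house=max(config.sigma_add_house, 1e-12),
        sigma_add_secondary=max(config.sigma_add_secondary, 1e-12),
        sigma_add_subopt=max(config.sigma_add_subopt, 1e-12),
        sigma_eps=max(config.sigma_eps, 1e-12),
    )
    if len(params.gamma_age) != space.n_knots:
        raise ValidationError("gamma_age truth must have one value per knot")

    # populations: single years of age 20..99
    pop_rows = []
    ages = np.arange(20, 100)
    for c in hierarchy.countries:
        for yr in config.years:
            for sex in ("female", "male"):
                counts = rng_pop.integers(config.pop_min, config.pop_max, len(ages))
                for a, cnt in zip(ages, counts):
                    pop_rows.append((c, yr, sex, int(a), int(cnt)))
    populations = pd.DataFrame(
        pop_rows, columns=["country_id", "year", "sex", "age", "count"]
    )

    theta = space.pack(params)[: space.n_linear]
    pop_idx = {
        (r.country_id, r.year, r.sex): {} for r in populations.itertuples(index=False)
    }
    for r in populations.itertuples(index=False):
        pop_idx[(r.country_id, r.year, r.sex)][r.age] = r.count

    def base_eta(cell: Cell) -> float:
        row = space.design_row(
            country_id=cell.country_id,
            year=cell.year,
            sex=cell.sex,
            age_lo=cell.age_lo,
            age_hi=cell.age_hi,
            z_avail=0.0,
            pop_weights=pop_idx[(cell.country_id, cell.year, cell.sex)],
        )
        return float(row @ theta)

    cells = [
        Cell(c, yr, sex, lo, hi)
        for c in hierarchy.countries
        for yr in config.years
        for sex in ("female", "male")
        for lo, hi in config.age_bands
    ]
    base = {cell: base_eta(cell) for cell in cells}

    # population-mean base intake per (country, year), weighted over sex/band
    bi_rows = []
    for c in hierarchy.countries:
        for yr in config.years:
            w_total, acc = 0.0, 0.0
            for cell in cells:
                if cell.country_id == c and cell.year == yr:
                    w = sum(
                        cnt
                        for a, cnt in pop_idx[(c, yr, cell.sex)].items()
                        if cell.age_lo <= a < cell.age_hi
                    )
                    acc += w * np.exp(base[cell])
                    w_total += w
            bi_rows.append((c, yr, acc / w_total))
    base_intake = pd.DataFrame(bi_rows, columns=["country_id", "year", "base_intake"])

    availability = simulate_availability(base_intake, config, rng=rng_avail)
    availability = standardize_availability(availability)
    z = {
        (r.country_id, r.year): r.z_value for r in availability.itertuples(index=False)
    }

    surf_rows = [
        {
            "country_id": cell.country_id,
            "year": cell.year,
            "sex": cell.sex,
            "age_lo": cell.age_lo,
            "age_hi": cell.age_hi,
            "base_log": base[cell],
            "true_mean": float(
                np.exp(base[cell] + config.lambda_avail * z[(cell.country_id, cell.year)])
            ),
        }
        for cell in cells
    ]
    truth = GroundTruth(
        params=params,
        surface=pd.DataFrame(surf_rows),
        base_intake=base_intake,
        seed=config.seed,
    )
    return World(
        config=config,
        hierarchy=hierarchy,
        populations=populations,
        availability=availability,
        truth=truth,
        space=space,
    )


def simulate_availability(
    base_intake: pd.DataFrame,
    config: WorldConfig,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Country-year availability proxy: ``a + b * base intake + noise``.

    Coverage is complete — every country-year appears exactly once, the
    way food-balance sheets cover all countries regardless of survey
    activity.  Values are floored at 0 (availability is non-negative).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    if config.avail_slope == 0:
        log.warning("simulate_availability: slope b = 0; calibration is unidentifiable")
    noise = rng.normal(0.0, config.avail_noise_sd, len(base_intake))
    values = (
        config.avail_intercept
        + config.avail_slope * base_intake["base_intake"].to_numpy()
        + noise
    )
    return pd.DataFrame(
        {
            "country_id": base_intake["country_id"],
            "year": base_intake["year"],
            "beverage": "ssb",
            "value": np.maximum(values, 0.0),
        }
    )


def simulate_surveys(
    world: World, seed: int | None = None
) -> tuple[list[SurveyStratum], list[str]]:
    """Biased, noisy survey strata for a seeded subset of countries.

    A fraction ``survey_coverage`` of countries receives one survey per
    (year, sex, age band); the rest are availability-only (as much of
    Sub-Saharan Africa is in practice).  Each stratum samples its four
    data-quality flags, then observes
    ``truth * exp(sum of bias offsets + noise)`` with noise variance equal
    to the model's sampling + residual + non-preferred components — so the
    generating process matches the fitted likelihood.

    Returns the strata and the list of covered countries.
    """
    config = world.config
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    n_cov = max(1, round(config.survey_coverage * len(world.hierarchy.countries)))
    covered = sorted(
        rng.choice(world.hierarchy.countries, size=n_cov, replace=False).tolist()
    )
    truth = world.truth
    params = truth.params
    b = params.bias_offsets
    sigma_add2 = params.sigma_add**2
    cv, n = config.intake_cv, config.stratum_n
    se_log = cv / np.sqrt(n)

    strata = []
    for c in covered:
        for yr in config.years:
            for sex in ("female", "male"):
                for lo, hi in config.age_bands:
                    cell = Cell(c, yr, sex, lo, hi)
                    flags = np.array(
                        [
                            rng.uniform() < config.p_subnational,
                            rng.uniform() < config.p_household,
                            rng.uniform() < config.p_secondary,
                            rng.uniform() < config.p_suboptimal,
                        ],
                        dtype=float,
                    )
                    var = se_log**2 + params.sigma_eps**2 + float(flags @ sigma_add2)
                    log_obs = (
                        np.log(truth.true_mean(cell))
                        + float(flags @ b)
                        + rng.normal(0.0, np.sqrt(var))
                    )
                    mean = float(np.exp(log_obs))
                    strata.append(
                        SurveyStratum(
                            country_id=c,
                            year=yr,
                            sex=sex,
                            age_lo=lo,
                            age_hi=hi,
                            mean_intake=mean,
                            sd_intake=cv * mean,
                            n=n,
                            nationally_representative=not bool(flags[0]),
                            individual_level=not bool(flags[1]),
                            primary_metric=not bool(flags[2]),
                            optimal_assessment=not bool(flags[3]),
                            survey_id=f"SVY_{c}_{yr}",
                        )
                    )
    return strata, covered


def simulate_gni(world: World, seed: int | None = None) -> pd.DataFrame:
    """Per-capita GNI stand-in (log-uniform) with its World Bank class."""
    from .core_types import classify_income

    config = world.config
    rng = np.random.default_rng(config.seed + 4 if seed is None else seed)
    gni = np.exp(rng.uniform(config.gni_log_min, config.gni_log_max,
                             len(world.hierarchy.countries)))
    return pd.DataFrame(
        {
            "country_id": world.hierarchy.countries,
            "gni_per_capita": np.round(gni, 0),
            "income_class": [classify_income(g) for g in gni],
        }
    )


def simulate_bmi(world: World, seed: int | None = None) -> pd.DataFrame:
    """Country-stratum mean-BMI stand-in with a configured true correlation.

    Within each (year, sex, age band) stratum, country BMI is built from
    the standardized log true intake at correlation ``bmi_intake_corr``
    plus independent noise — a surrogate for externally supplied
    anthropometric estimates in cross-country correlation analyses.
    """
    config = world.config
    rng = np.random.default_rng(config.seed + 5 if seed is None else seed)
    rho = config.bmi_intake_corr
    rows = []
    surface = world.truth.surface
    for (year, sex, lo, hi), sub in surface.groupby(
        ["year", "sex", "age_lo", "age_hi"], sort=True
    ):
        x = np.log(sub["true_mean"].to_numpy())
        xs = (x - x.mean()) / x.std(ddof=0) if x.std(ddof=0) > 0 else np.zeros_like(x)
        noise = rng.standard_normal(len(sub))
        bmi = config.bmi_mean + config.bmi_sd * (
            rho * xs + np.sqrt(1.0 - rho**2) * noise
        )
        for country, value in zip(sub["country_id"], bmi):
            rows.append(
                {
                    "country_id": country,
                    "year": year,
                    "sex": sex,
                    "age_lo": lo,
                    "age_hi": hi,
                    "mean": float(value),
                }
            )
    return pd.DataFrame(rows)


def simulate_recalls(
    world: World,
    cell: Cell,
    seed: int | None = None,
    n_persons: int | None = None,
) -> list[RecallRecord]:
    """Per-person repeated 24-hour recalls for one stratum.

    Person-level usual intakes scatter around the cell truth with SD
    ``between_sd``; each recall day adds within-person noise with SD
    ``within_sd``.  Person-level energy is correlated with usual intake
    at ``energy_intake_corr``.  Day values are floored at zero (logged
    when it happens); defaults keep flooring negligible.
    """
    config = world.config
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    n_persons = n_persons or config.recall_persons
    mu = world.truth.true_mean(cell)
    z_intake = rng.standard_normal(n_persons)
    person_true = mu + config.between_sd * z_intake
    rho = config.energy_intake_corr
    z2 = rng.standard_normal(n_persons)
    energy = config.energy_mean + config.energy_sd * (
        rho * z_intake + np.sqrt(1 - rho**2) * z2
    )
    records = []
    n_floored = 0
    mid_age = (cell.age_lo + cell.age_hi) / 2
    for i in range(n_persons):
        for day in range(1, config.recall_days + 1):
            value = person_true[i] + rng.normal(0.0, config.within_sd)
            if value < 0:
                n_floored += 1
                value = 0.0
            records.append(
                RecallRecord(
                    person_id=f"P{i:05d}",
                    survey_id=f"SVY_{cell.country_id}_{cell.year}",
                    day_index=day,
                    intake=float(value),
                    energy=float(energy[i] + rng.normal(0.0, 50.0)),
                    weight=1.0,
                    country_id=cell.country_id,
                    year=cell.year,
                    sex=cell.sex,
                    age=mid_age,
                )
            )
    if n_floored:
        log.info("simulate_recalls: floored %d negative day values at 0", n_floored)
    return records
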