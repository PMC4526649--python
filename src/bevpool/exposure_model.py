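"""Age-integrating Bayesian hierarchical model of beverage intake.

The model pools heterogeneous survey strata on the log-intake scale.  For
stratum *i* covering ages ``[lo_i, hi_i)`` in country *c*, year *t*:

    y_i ~ Normal(mu_i, se_i^2 + sigma_eps^2 + sum_k sigma_add_k^2 * flag_ik)

    mu_i = beta0 + A(lo_i, hi_i) + delta_sex * male_i + phi_t * (t - 2000)/10
           + lambda_avail * z_{c,t} + u_super(c) + u_region(c) + u_country(c)
           + sum_k b_k * flag_ik

where ``A`` is the population-weighted average over the stratum's age range
of a piecewise-linear age curve on decade knots (anchored to 0 at age 20),
``z`` is standardized food-balance availability, the four ``flag_k``
indicators mark non-preferred data characteristics (subnational,
household-level, secondary metric, suboptimal assessment), the ``b_k`` are
their additive bias offsets and the ``sigma_add_k`` their extra variance
components — non-preferred observations are both shifted to the preferred
standard and down-weighted.  Country effects nest in region effects nest
in super-region effects, each with its own SD; the availability covariate
carries information into country-years with no survey at all.

The module exposes the unnormalized log posterior both on natural-scale
parameters (:class:`ModelParams`) and on a packed real vector (SDs on the
log scale with the Jacobian included) for the Metropolis sampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_types import RegionHierarchy, SurveyStratum, ValidationError

__all__ = [
    "DEFAULT_KNOTS",
    "ModelConfig",
    "ModelParams",
    "ObservationLikelihoodInput",
    "log_transform_obs",
    "age_basis",
    "age_curve",
    "age_band_basis",
    "integrate_age",
    "standardize_availability",
    "availability_z_lookup",
    "ParameterSpace",
    "BeverageModel",
]

#: Decade knots of the piecewise-linear age curve (top band wider: 80-100).
DEFAULT_KNOTS = (20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 100.0)

_HALF_NORMAL_CONST = 0.5 * math.log(2.0 / math.pi)

FLAG_NAMES = ("subnational", "household", "secondary", "suboptimal")


@dataclass(frozen=True)
class ModelConfig:
    """Tunables of the likelihood and priors.

    ``intake_floor`` (servings/day) keeps near-zero strata on the log
    scale; ``se_floor`` is the minimum log-scale standard error so no
    single stratum becomes infinitely informative; ``ref_year`` centres
    the time slope; fixed effects get N(0, fixed_effect_sd^2) priors and
    every SD parameter a Half-Normal(sd_prior_scale) prior.
    """

    knots: tuple[float, ...] = DEFAULT_KNOTS
    intake_floor: float = 0.005
    se_floor: float = 0.01
    ref_year: float = 2000.0
    fixed_effect_sd: float = 10.0
    sd_prior_scale: float = 1.0
    #: SD of the age-curve's per-decade random-walk increments (log scale).
    #: Smoothness ties knots that wide survey age bands leave unobserved to
    #: their identified neighbours; without it those directions carry the
    #: diffuse fixed-effect prior and the posterior becomes a ridge.
    age_rw_scale: float = 0.5


@dataclass
class ModelParams:
    """Full parameter vector on the natural scale.

    ``gamma_age`` has one coefficient per knot with the first (age 20)
    fixed at 0 for identifiability; ``u_s/u_r/u_c`` align with the sorted
    super-region/region/country orderings of the hierarchy.
    """

    beta0: float = 0.0
    gamma_age: np.ndarray = field(default_factory=lambda: np.zeros(len(DEFAULT_KNOTS)))
    delta_sex: float = 0.0
    phi_t: float = 0.0
    lambda_avail: float = 0.0
    b_sub: float = 0.0
    b_house: float = 0.0
    b_secondary: float = 0.0
    b_subopt: float = 0.0
    u_s: np.ndarray = field(default_factory=lambda: np.zeros(0))
    u_r: np.ndarray = field(default_factory=lambda: np.zeros(0))
    u_c: np.ndarray = field(default_factory=lambda: np.zeros(0))
    tau_s: float = 1.0
    tau_r: float = 1.0
    tau_c: float = 1.0
    sigma_add_sub: float = 0.1
    sigma_add_house: float = 0.1
    sigma_add_secondary: float = 0.1
    sigma_add_subopt: float = 0.1
    sigma_eps: float = 0.1

    @property
    def bias_offsets(self) -> np.ndarray:
        return np.array([self.b_sub, self.b_house, self.b_secondary, self.b_subopt])

    @property
    def sigma_add(self) -> np.ndarray:
        return np.array(
            [
                self.sigma_add_sub,
                self.sigma_add_house,
                self.sigma_add_secondary,
                self.sigma_add_subopt,
            ]
        )

    @property
    def sds(self) -> np.ndarray:
        return np.concatenate(
            ([self.tau_s, self.tau_r, self.tau_c], self.sigma_add, [self.sigma_eps])
        )


@dataclass(frozen=True)
class ObservationLikelihoodInput:
    """One stratum transformed to the model's likelihood scale."""

    y: float
    se_y: float
    age_lo: int
    age_hi: int
    sex: str
    country_id: str
    year: int
    subnational: bool
    household: bool
    secondary: bool
    suboptimal: bool
    z_avail: float = 0.0
    floored: bool = False

    @property
    def flags(self) -> np.ndarray:
        return np.array(
            [self.subnational, self.household, self.secondary, self.suboptimal],
            dtype=float,
        )


def log_transform_obs(
    stratum: SurveyStratum,
    z_avail: float = 0.0,
    config: ModelConfig = ModelConfig(),
) -> ObservationLikelihoodInput:
    """Delta-method transform of a stratum to the log scale.

    ``y = ln(m)`` and ``se_y = (s / sqrt(n)) / m`` with the mean floored at
    ``config.intake_floor`` (flagged) and the SE floored at
    ``config.se_floor``.
    """
    if stratum.n < 1:
        raise ValidationError("stratum has n < 1")
    m = stratum.mean_intake
    floored = m < config.intake_floor
    m = max(m, config.intake_floor)
    se = (stratum.sd_intake / math.sqrt(stratum.n)) / m
    se = max(se, config.se_floor)
    return ObservationLikelihoodInput(
        y=math.log(m),
        se_y=se,
        age_lo=stratum.age_lo,
        age_hi=stratum.age_hi,
        sex=stratum.sex,
        country_id=stratum.country_id,
        year=stratum.year,
        subnational=not stratum.nationally_representative,
        household=not stratum.individual_level,
        secondary=not stratum.primary_metric,
        suboptimal=not stratum.optimal_assessment,
        z_avail=float(z_avail),
        floored=floored,
    )


# ---------------------------------------------------------------------------
# Age curve
# ---------------------------------------------------------------------------


def age_basis(age: float, knots: Sequence[float] = DEFAULT_KNOTS) -> np.ndarray:
    """Hat-function weights of one age over the knots (sum to 1)."""
    knots = np.asarray(knots, dtype=float)
    if age < knots[0] or age > knots[-1]:
        raise ValidationError(f"age {age} outside [{knots[0]}, {knots[-1]}]")
    w = np.zeros(len(knots))
    j = int(np.searchsorted(knots, age, side="right")) - 1
    if j >= len(knots) - 1:  # exactly at the top knot
        w[-1] = 1.0
        return w
    frac = (age - knots[j]) / (knots[j + 1] - knots[j])
    w[j] = 1.0 - frac
    w[j + 1] = frac
    return w


def age_curve(
    gamma_age: Sequence[float], age: float, knots: Sequence[float] = DEFAULT_KNOTS
) -> float:
    """Piecewise-linear age effect at a single age (log-intake scale)."""
    gamma = np.asarray(gamma_age, dtype=float)
    if len(gamma) != len(knots):
        raise ValidationError(
            f"gamma_age has {len(gamma)} coefficients for {len(knots)} knots"
        )
    return float(age_basis(age, knots) @ gamma)


def age_band_basis(
    age_lo: float,
    age_hi: float,
    pop_weights: Mapping[int, float] | pd.Series | None = None,
    knots: Sequence[float] = DEFAULT_KNOTS,
) -> np.ndarray:
    """Population-weighted average of hat weights over integer ages in [lo, hi).

    This row vector turns the continuous age curve into the model's
    prediction for an observation reported over an age range; uniform
    weights are used when no population slice is supplied.
    """
    if not age_lo < age_hi:
        raise ValidationError(f"require age_lo < age_hi, got [{age_lo}, {age_hi})")
    ages = np.arange(int(age_lo), int(age_hi))
    if pop_weights is None:
        w = np.ones(len(ages))
    else:
        getter = pop_weights.get if hasattr(pop_weights, "get") else pop_weights.__getitem__
        w = np.array([float(getter(int(a), 0.0)) for a in ages])
    total = w.sum()
    if not total > 0:
        raise ValidationError(
            f"population weights over [{age_lo}, {age_hi}) are empty or all zero"
        )
    rows = np.stack([age_basis(a, knots) for a in ages])
    return (w / total) @ rows


def integrate_age(
    gamma_age: Sequence[float],
    age_lo: float,
    age_hi: float,
    pop_weights: Mapping[int, float] | pd.Series | None = None,
    knots: Sequence[float] = DEFAULT_KNOTS,
) -> float:
    """Interval-average age effect over [age_lo, age_hi)."""
    basis = age_band_basis(age_lo, age_hi, pop_weights, knots)
    return float(basis @ np.asarray(gamma_age, dtype=float))


# ---------------------------------------------------------------------------
# Availability covariate
# ---------------------------------------------------------------------------


def standardize_availability(availability: pd.DataFrame) -> pd.DataFrame:
    """Fill ``z_value`` by z-scoring ``value`` over all country-years.

    Standardization is per beverage (when a ``beverage`` column is
    present).  The availability coefficient learned from surveyed
    countries then applies everywhere — this is how food-balance data
    calibrate estimates for countries with no surveys.
    """
    df = availability.copy()

    def _z(series: pd.Series) -> pd.Series:
        sd = series.std(ddof=0)
        if not sd > 0:
            raise ValidationError("availability series has zero variance")
        return (series - series.mean()) / sd

    if "beverage" in df.columns and df["beverage"].nunique() > 1:
        df["z_value"] = df.groupby("beverage")["value"].transform(_z)
    else:
        df["z_value"] = _z(df["value"])
    return df


def availability_z_lookup(
    availability: pd.DataFrame, beverage: str | None = None
) -> dict[tuple[str, int], float]:
    """Map (country_id, year) -> z_value, standardizing first if needed."""
    df = availability
    if "z_value" not in df.columns or df["z_value"].isna().any():
        df = standardize_availability(df)
    if beverage is not None and "beverage" in df.columns:
        df = df[df["beverage"] == beverage]
    return {
        (str(r.country_id), int(r.year)): float(r.z_value)
        for r in df.itertuples(index=False)
    }


# ---------------------------------------------------------------------------
# Parameter space: ordering, packing, priors
# ---------------------------------------------------------------------------


class ParameterSpace:
    """Layout of the packed parameter vector for a given hierarchy.

    Packed order: ``beta0``, free age-knot coefficients (knots[1:]),
    ``delta_sex``, ``phi_t``, ``lambda_avail``, the four bias offsets,
    super-region / region / country random intercepts, then the eight SD
    parameters on the log scale.  Everything before the log-SD block is
    linear in the predictor, so ``mu = X @ vec[:n_linear]``.
    """

    def __init__(self, hierarchy: RegionHierarchy, config: ModelConfig = ModelConfig()):
        self.hierarchy = hierarchy
        self.config = config
        self.knots = tuple(config.knots)
        self.n_knots = len(self.knots)
        self.supers = list(hierarchy.super_regions)
        self.regions = list(hierarchy.regions)
        self.countries = list(hierarchy.countries)
        self._s_index = {s: i for i, s in enumerate(self.supers)}
        self._r_index = {r: i for i, r in enumerate(self.regions)}
        self._c_index = {c: i for i, c in enumerate(self.countries)}
        k = self.n_knots - 1
        self.n_fixed = 1 + k + 3 + 4
        self.n_linear = self.n_fixed + len(self.supers) + len(self.regions) + len(
            self.countries
        )
        self.n_sd = 8  # tau_s, tau_r, tau_c, four sigma_add, sigma_eps
        self.dim = self.n_linear + self.n_sd
        self.sl_gamma = slice(1, 1 + k)
        base = 1 + k
        self.i_delta, self.i_phi, self.i_lambda = base, base + 1, base + 2
        self.sl_bias = slice(base + 3, base + 7)
        self.sl_us = slice(self.n_fixed, self.n_fixed + len(self.supers))
        self.sl_ur = slice(self.sl_us.stop, self.sl_us.stop + len(self.regions))
        self.sl_uc = slice(self.sl_ur.stop, self.sl_ur.stop + len(self.countries))
        self.sl_logsd = slice(self.n_linear, self.dim)
        # per-increment variances of the age-curve random-walk prior,
        # proportional to knot spacing in decades
        spacings = np.diff(np.asarray(self.knots)) / 10.0
        self.age_rw_var = (config.age_rw_scale**2) * spacings
        self.names = (
            ["beta0"]
            + [f"gamma_age_{int(kn)}" for kn in self.knots[1:]]
            + ["delta_sex", "phi_t", "lambda_avail"]
            + ["b_sub", "b_house", "b_secondary", "b_subopt"]
            + [f"u_s[{s}]" for s in self.supers]
            + [f"u_r[{r}]" for r in self.regions]
            + [f"u_c[{c}]" for c in self.countries]
            + [
                "log_tau_s",
                "log_tau_r",
                "log_tau_c",
                "log_sigma_add_sub",
                "log_sigma_add_house",
                "log_sigma_add_secondary",
                "log_sigma_add_subopt",
                "log_sigma_eps",
            ]
        )

    # -- design rows -------------------------------------------------------

    def design_row(
        self,
        *,
        country_id: str,
        year: float,
        sex: str,
        age_lo: float,
        age_hi: float,
        z_avail: float,
        flags: Sequence[float] = (0.0, 0.0, 0.0, 0.0),
        pop_weights: Mapping[int, float] | None = None,
    ) -> np.ndarray:
        """Linear-predictor row for one observation or prediction cell."""
        if country_id not in self.hierarchy:
            raise ValidationError(f"unknown country {country_id!r}")
        row = np.zeros(self.n_linear)
        row[0] = 1.0
        row[self.sl_gamma] = age_band_basis(age_lo, age_hi, pop_weights, self.knots)[1:]
        row[self.i_delta] = 1.0 if sex == "male" else 0.0
        row[self.i_phi] = (year - self.config.ref_year) / 10.0
        row[self.i_lambda] = z_avail
        row[self.sl_bias] = np.asarray(flags, dtype=float)
        row[self.sl_us.start + self._s_index[self.hierarchy.super_region_of(country_id)]] = 1.0
        row[self.sl_ur.start + self._r_index[self.hierarchy.region_of(country_id)]] = 1.0
        row[self.sl_uc.start + self._c_index[country_id]] = 1.0
        return row

    # -- pack / unpack -----------------------------------------------------

    def pack(self, params: ModelParams) -> np.ndarray:
        vec = np.empty(self.dim)
        vec[0] = params.beta0
        gamma = np.asarray(params.gamma_age, dtype=float)
        if len(gamma) != self.n_knots:
            raise ValidationError("gamma_age length does not match knots")
        if gamma[0] != 0.0:
            raise ValidationError("gamma_age[0] (age-20 knot) must be 0")
        vec[self.sl_gamma] = gamma[1:]
        vec[self.i_delta] = params.delta_sex
        vec[self.i_phi] = params.phi_t
        vec[self.i_lambda] = params.lambda_avail
        vec[self.sl_bias] = params.bias_offsets
        vec[self.sl_us] = params.u_s
        vec[self.sl_ur] = params.u_r
        vec[self.sl_uc] = params.u_c
        sds = params.sds
        if np.any(sds <= 0):
            raise ValidationError("all SD parameters must be > 0")
        vec[self.sl_logsd] = np.log(sds)
        return vec

    def unpack(self, vec: np.ndarray) -> ModelParams:
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (self.dim,):
            raise ValidationError(f"expected vector of length {self.dim}")
        sds = np.exp(vec[self.sl_logsd])
        return ModelParams(
            beta0=float(vec[0]),
            gamma_age=np.concatenate(([0.0], vec[self.sl_gamma])),
            delta_sex=float(vec[self.i_delta]),
            phi_t=float(vec[self.i_phi]),
            lambda_avail=float(vec[self.i_lambda]),
            b_sub=float(vec[self.sl_bias][0]),
            b_house=float(vec[self.sl_bias][1]),
            b_secondary=float(vec[self.sl_bias][2]),
            b_subopt=float(vec[self.sl_bias][3]),
            u_s=vec[self.sl_us].copy(),
            u_r=vec[self.sl_ur].copy(),
            u_c=vec[self.sl_uc].copy(),
            tau_s=float(sds[0]),
            tau_r=float(sds[1]),
            tau_c=float(sds[2]),
            sigma_add_sub=float(sds[3]),
            sigma_add_house=float(sds[4]),
            sigma_add_secondary=float(sds[5]),
            sigma_add_subopt=float(sds[6]),
            sigma_eps=float(sds[7]),
        )

    def blank_params(self) -> ModelParams:
        return ModelParams(
            gamma_age=np.zeros(self.n_knots),
            u_s=np.zeros(len(self.supers)),
            u_r=np.zeros(len(self.regions)),
            u_c=np.zeros(len(self.countries)),
        )


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------


def _normal_logpdf(x, mu, var):
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mu) ** 2 / var)


class BeverageModel:
    """Likelihood, priors and log posterior for a set of observations.

    Builds the dense design matrix once; the packed log posterior is a
    handful of vectorized operations per evaluation, which is what the
    Metropolis sampler calls.
    """

    def __init__(
        self,
        obs: Iterable[ObservationLikelihoodInput],
        hierarchy: RegionHierarchy,
        config: ModelConfig = ModelConfig(),
        populations: pd.DataFrame | None = None,
    ):
        self.space = ParameterSpace(hierarchy, config)
        self.config = config
        self.obs = list(obs)
        if not self.obs:
            raise ValidationError("no observations supplied")
        pop_by = _population_age_weights(populations)
        rows, flags = [], []
        for o in self.obs:
            if not np.isfinite(o.y):
                raise ValidationError(f"non-finite observation y for {o.country_id}")
            if not o.se_y > 0:
                raise ValidationError("se_y must be > 0")
            w = pop_by.get((o.country_id, o.year, o.sex)) if pop_by else None
            rows.append(
                self.space.design_row(
                    country_id=o.country_id,
                    year=o.year,
                    sex=o.sex,
                    age_lo=o.age_lo,
                    age_hi=o.age_hi,
                    z_avail=o.z_avail,
                    flags=o.flags,
                    pop_weights=w,
                )
            )
            flags.append(o.flags)
        self.X = np.stack(rows)
        self.F = np.stack(flags)
        self.Xf = self.X[:, : self.space.n_fixed]
        self.Z = self.X[:, self.space.n_fixed : self.space.n_linear]
        self.y = np.array([o.y for o in self.obs])
        self.se2 = np.array([o.se_y**2 for o in self.obs])

    # -- natural-scale operations -----------------------------------------

    def linear_predictor(
        self, params: ModelParams, obs: ObservationLikelihoodInput
    ) -> float:
        """Predicted log intake for a single observation."""
        row = self.space.design_row(
            country_id=obs.country_id,
            year=obs.year,
            sex=obs.sex,
            age_lo=obs.age_lo,
            age_hi=obs.age_hi,
            z_avail=obs.z_avail,
            flags=obs.flags,
        )
        return float(row @ self._theta_linear(params))

    def _theta_linear(self, params: ModelParams) -> np.ndarray:
        return self.space.pack(params)[: self.space.n_linear]

    def log_likelihood(self, params: ModelParams) -> float:
        theta = self._theta_linear(params)
        mu = self.X @ theta
        var = self.se2 + params.sigma_eps**2 + self.F @ params.sigma_add**2
        return float(np.sum(_normal_logpdf(self.y, mu, var)))

    def log_prior(self, params: ModelParams) -> float:
        """Priors: scalar fixed effects N(0, s^2); age-curve increments
        random-walk N(0, rw-scale^2 per decade); nested intercepts
        N(0, tau^2); SDs Half-Normal(scale)."""
        sds = params.sds
        if np.any(sds <= 0):
            return -np.inf
        cfg = self.config
        fixed = np.concatenate(
            (
                [params.beta0],
                [params.delta_sex, params.phi_t, params.lambda_avail],
                params.bias_offsets,
            )
        )
        lp = float(np.sum(_normal_logpdf(fixed, 0.0, cfg.fixed_effect_sd**2)))
        inc = np.diff(np.asarray(params.gamma_age, dtype=float))
        lp += float(np.sum(_normal_logpdf(inc, 0.0, self.space.age_rw_var)))
        lp += float(np.sum(_normal_logpdf(params.u_s, 0.0, params.tau_s**2)))
        lp += float(np.sum(_normal_logpdf(params.u_r, 0.0, params.tau_r**2)))
        lp += float(np.sum(_normal_logpdf(params.u_c, 0.0, params.tau_c**2)))
        scale = cfg.sd_prior_scale
        lp += float(
            np.sum(
                _HALF_NORMAL_CONST - np.log(scale) - 0.5 * (sds / scale) ** 2
            )
        )
        return lp

    def log_posterior(self, params: ModelParams) -> float:
        lp = self.log_prior(params)
        if not np.isfinite(lp):
            return -np.inf
        return lp + self.log_likelihood(params)

    # -- packed fast path (what the sampler evaluates) ---------------------

    def packed_log_posterior(self, vec: np.ndarray) -> float:
        """Log posterior on the full packed vector (SDs on the log scale,
        change-of-variables Jacobian included)."""
        sp = self.space
        log_sd = vec[sp.sl_logsd]
        if np.any(np.abs(log_sd) > 50):  # guard exp overflow far in the tails
            return -np.inf
        sds = np.exp(log_sd)
        tau2 = sds[:3] ** 2
        sigma_add2 = sds[3:7] ** 2
        sigma_eps2 = sds[7] ** 2

        mu = self.X @ vec[: sp.n_linear]
        var = self.se2 + sigma_eps2 + self.F @ sigma_add2
        ll = np.sum(_normal_logpdf(self.y, mu, var))

        lp = self._fixed_log_prior(vec)
        lp += np.sum(_normal_logpdf(vec[sp.sl_us], 0.0, tau2[0]))
        lp += np.sum(_normal_logpdf(vec[sp.sl_ur], 0.0, tau2[1]))
        lp += np.sum(_normal_logpdf(vec[sp.sl_uc], 0.0, tau2[2]))
        lp += self._sd_log_prior(sds, log_sd)
        return float(ll + lp)

    def _fixed_log_prior(self, vec: np.ndarray) -> float:
        sp, cfg = self.space, self.config
        gamma = np.concatenate(([0.0], vec[sp.sl_gamma]))
        scalars = np.concatenate((vec[:1], vec[sp.sl_gamma.stop : sp.n_fixed]))
        lp = np.sum(_normal_logpdf(scalars, 0.0, cfg.fixed_effect_sd**2))
        lp += np.sum(_normal_logpdf(np.diff(gamma), 0.0, sp.age_rw_var))
        return float(lp)

    def _sd_log_prior(self, sds: np.ndarray, log_sd: np.ndarray) -> float:
        scale = self.config.sd_prior_scale
        lp = np.sum(_HALF_NORMAL_CONST - math.log(scale) - 0.5 * (sds / scale) ** 2)
        return float(lp + np.sum(log_sd))  # + Jacobian sd -> log sd

    # -- marginalized target (what the pipeline samples) -------------------
    #
    # The random intercepts are jointly Gaussian given the variance
    # parameters, so they can be integrated out of the likelihood in
    # closed form:  y ~ N(Xf theta_f, D + Z G Z') with D the diagonal
    # observation variance and G = diag(tau^2 by level).  The Metropolis
    # chain then explores only the fixed effects and the eight (log) SDs
    # — 23 well-conditioned dimensions with no funnel geometry — and the
    # intercepts are reconstructed exactly from their conditional Gaussian
    # for each posterior draw (u | y, rest ~ N(M^-1 Z' D^-1 r, M^-1) with
    # M = G^-1 + Z' D^-1 Z).

    @property
    def marginal_dim(self) -> int:
        return self.space.n_fixed + self.space.n_sd

    @property
    def marginal_names(self) -> list[str]:
        sp = self.space
        return sp.names[: sp.n_fixed] + sp.names[sp.sl_logsd]

    def _marginal_pieces(self, vec: np.ndarray):
        sp = self.space
        theta_f = vec[: sp.n_fixed]
        log_sd = vec[sp.n_fixed :]
        if np.any(np.abs(log_sd) > 50):
            return None
        sds = np.exp(log_sd)
        tau2 = sds[:3] ** 2
        g_diag = np.concatenate(
            (
                np.full(len(sp.supers), tau2[0]),
                np.full(len(sp.regions), tau2[1]),
                np.full(len(sp.countries), tau2[2]),
            )
        )
        d = self.se2 + sds[7] ** 2 + self.F @ (sds[3:7] ** 2)
        r = self.y - self.Xf @ theta_f
        zd = self.Z.T / d  # (q, n)
        m = np.diag(1.0 / g_diag) + zd @ self.Z
        return theta_f, log_sd, sds, g_diag, d, r, zd, m

    def marginal_log_posterior(self, vec: np.ndarray) -> float:
        pieces = self._marginal_pieces(np.asarray(vec, dtype=float))
        if pieces is None:
            return -np.inf
        theta_f, log_sd, sds, g_diag, d, r, zd, m = pieces
        try:
            chol = np.linalg.cholesky(m)
        except np.linalg.LinAlgError:
            return -np.inf
        zdr = zd @ r
        w = np.linalg.solve(chol, zdr)
        quad = float(r @ (r / d) - w @ w)
        logdet = (
            float(np.sum(np.log(d)))
            + float(np.sum(np.log(g_diag)))
            + 2.0 * float(np.sum(np.log(np.diag(chol))))
        )
        n = len(self.y)
        ll = -0.5 * (n * math.log(2.0 * math.pi) + logdet + quad)
        lp = self._fixed_log_prior(theta_f)
        lp += self._sd_log_prior(sds, log_sd)
        return float(ll + lp)

    def draw_random_effects(self, vec: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Exact conditional draw of all random intercepts given one
        marginal-parameter vector (countries with no surveys get properly
        correlated prior draws)."""
        pieces = self._marginal_pieces(np.asarray(vec, dtype=float))
        if pieces is None:
            raise ValidationError("marginal vector out of support")
        theta_f, log_sd, sds, g_diag, d, r, zd, m = pieces
        chol = np.linalg.cholesky(m)
        u_hat = np.linalg.solve(chol.T, np.linalg.solve(chol, zd @ r))
        z = rng.standard_normal(len(u_hat))
        return u_hat + np.linalg.solve(chol.T, z)

    def expand_marginal(self, vec: np.ndarray, u: np.ndarray) -> np.ndarray:
        """Assemble a full packed vector from marginal params + intercepts."""
        sp = self.space
        full = np.empty(sp.dim)
        full[: sp.n_fixed] = vec[: sp.n_fixed]
        full[sp.n_fixed : sp.n_linear] = u
        full[sp.sl_logsd] = vec[sp.n_fixed :]
        return full

    def marginal_init_vector(self) -> np.ndarray:
        vec = np.zeros(self.marginal_dim)
        vec[0] = float(np.mean(self.y))
        vec[self.space.n_fixed :] = math.log(0.2)
        return vec

    def init_vector(self) -> np.ndarray:
        """Starting point: intercept at the data mean, SDs at moderate values."""
        vec = np.zeros(self.space.dim)
        vec[0] = float(np.mean(self.y))
        vec[self.space.sl_logsd] = math.log(0.2)
        return vec


def _population_age_weights(
    populations: pd.DataFrame | None,
) -> dict[tuple[str, int, str], dict[int, float]] | None:
    """Index population counts as (country, year, sex) -> {age: count}."""
    if populations is None:
        return None
    out: dict[tuple[str, int, str], dict[int, float]] = {}
    for r in populations.itertuples(index=False):
        key = (str(r.country_id), int(r.year), str(r.sex))
        out.setdefault(key, {})[int(r.age)] = float(r.count)
    return out
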