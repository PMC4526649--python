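# Methods

## The estimation problem

National estimates of beverage intake (sugar-sweetened beverages, fruit
juice, milk, and dietary calcium as a milk tracer) must be assembled from
surveys that differ in representativeness (national vs subnational),
measurement unit (individual vs household), dietary metric (primary vs
secondary) and assessment quality (optimal vs suboptimal), and that cover
only part of the world. Country-year food-balance availability series
(total sugar as the SSB proxy, total fruit for juice, milk directly) are
complete for every country and year, but measure availability, not
intake. `bevpool` pools these sources in one Bayesian hierarchical model
and propagates uncertainty by the draw.

## Observation model

Each survey stratum — a country-year-sex-age-range mean intake `m` with
SD `s` and sample size `n` — enters on the log scale by the delta
method: `y = ln m`, `se_y = (s/√n)/m`, with `m` floored at 0.005
servings/day (near-zero strata exist in real data) and `se_y` floored at
0.01 so no stratum becomes infinitely informative. The likelihood is

    y_i ~ Normal(mu_i,  se_i² + σ_eps² + Σ_k σ_add,k² · flag_ik)

    mu_i = β0 + A(lo_i, hi_i) + δ_sex·[male] + φ_t·(t−2000)/10
           + λ·z_ct + u_s + u_r + u_c + Σ_k b_k · flag_ik

The four flags mark non-preferred characteristics; each carries an
additive bias offset `b_k` (the crosswalk onto the preferred,
national/individual/primary/optimal standard) and an extra variance
component `σ_add,k` (the down-weighting of non-preferred data). Country
intercepts `u_c` nest in region intercepts `u_r` nest in super-region
intercepts `u_s`, each level with its own SD, so estimates for
data-sparse countries shrink toward their region.

**Age integration.** The age effect `A` is a piecewise-linear curve on
knots {20, 30, 40, 50, 60, 70, 80, 100} anchored to 0 at age 20. An
observation covering `[lo, hi)` is matched to the population-weighted
mean of the curve over the integer ages in the interval (uniform weights
when no population table is supplied), so surveys reporting wide or
idiosyncratic age bands still inform the continuous curve. The open-ended
"80+" band is closed at 100.

**Availability calibration.** Availability values are z-scored across all
country-years per beverage; the coefficient `λ` is learned from
country-years that have surveys and applied everywhere, which is what
lets countries with no surveys borrow strength from their food-balance
series as well as from their region.

## Priors

* scalar fixed effects (β0, δ_sex, φ_t, λ, b_k): Normal(0, 10²);
* age-curve increments between adjacent knots: Normal(0, 0.5² per
  decade), a random-walk smoothness prior (`age_rw_scale`, default 0.5).
  Wide survey age bands observe only combinations of knots; under a
  diffuse prior the unobserved knot directions form ridges of scale 10
  that a random-walk sampler cannot traverse, while the smoothness prior
  ties them to identified neighbours. 0.5 per decade allows a 65% change
  in intake per decade of age at one prior SD — far more age gradient
  than beverage intakes show;
* random intercepts: u_level ~ Normal(0, τ_level²);
* all SDs (τ_s, τ_r, τ_c, four σ_add, σ_eps): Half-Normal(1) on the
  log-intake scale, sampled as log-SDs with the Jacobian included.

All prior scales sit in `ModelConfig` and are overridable per run.

## Sampling

The sampler is an adaptive Metropolis random walk: a fixed diagonal
proposal (SD 0.1 per coordinate) for the first `max(100, 10·d)`
iterations, then Gaussian proposals with covariance `s_d·(Cov(history)
+ 10⁻⁶·I)`, `s_d = 2.38²/d`, adapting for the whole run (vanishing
adaptation). Every entry point takes an explicit seed and is
bit-reproducible.

The pipeline does not run the chain on the full parameter vector.
Because the random intercepts are jointly Gaussian given the variance
parameters, they are integrated out of the likelihood in closed form
(`y ~ N(X_f θ_f, D + Z G Zᵀ)`, evaluated via the Woodbury identity), and
the chain explores only the fixed effects and the eight log-SDs — 23
dimensions with no funnel geometry. For each kept state the intercepts
are then drawn exactly from their conditional Gaussian
`u | y ~ N(M⁻¹ZᵀD⁻¹r, M⁻¹)`, `M = G⁻¹ + ZᵀD⁻¹Z`; countries without
surveys receive properly correlated prior draws. This
Rao-Blackwellization was adopted after the flat joint chain proved
impractical: the centered parameterization funnels between each τ and
its intercept block, and split R-hat stayed near 2 after 40k iterations,
versus ~1.1 at 24k iterations for the marginal chain. The joint
log-posterior remains exposed (`BeverageModel.packed_log_posterior`) and
the marginalization is verified against it exactly in the tests.

Diagnostics: split Gelman-Rubin R-hat across chains and effective sample
size from FFT autocovariance with Geyer's initial monotone sequence
(cross-checked against ArviZ). The pipeline's convergence rule — fail
when max split R-hat ≥ 1.1 or min ESS ≤ 100 — is enforced by the CLI
`fit` command and available as `check_convergence=True` in the library.

Default fit settings (4 chains × 24k iterations, burn-in half, thin 4;
2 chains in the replicated test loops) were chosen from these
diagnostics on default synthetic worlds.

## Reporting surface

1,000 posterior parameter draws are taken from the pooled chains (evenly
strided when enough samples are kept, else bootstrap). Every reported
cell — country, year, sex, age band — is `exp(linear predictor)` per
draw with all flags at their preferred level, i.e. debiased to the
national-individual-primary-optimal standard. Draw *j* of every cell
comes from the same parameter draw, so population-weighted aggregates
(region, super-region, income class, globe), 1990→2010 differences and
their 95% intervals are computed within draws and inherit the full
correlation structure. Point estimates are draw means; intervals are the
2.5th/97.5th percentiles with linear interpolation between order
statistics (numpy's `linear` method — the definition matters at exactly
1,000 draws and is pinned by an independent sort-and-interpolate oracle
in the tests). A difference is called non-significant when the 95%
interval of the absolute difference contains 0. Cross-country Pearson
correlations (e.g. milk intake vs calcium, intake vs BMI) are computed
within sex/age strata on posterior-mean estimates; strata with fewer
than 3 paired countries or zero variance are reported missing.

## Survey preprocessing

Per-person recall microdata are harmonized before modelling:

* recall days are averaged per person; duplicate (person, day) rows are
  rejected;
* person means are energy-standardized by the residual method to
  2000 kcal/day (residual from the OLS line of intake on energy, plus
  the fitted value at 2000 kcal). Applied at the person level because
  usual intake is a person-level quantity. Identical energies make the
  slope undefined — the raw values pass through with a log note.
  Negative adjusted intakes are floored at 0 (count logged);
* the stratum SD is the between-person SD from the variance
  decomposition: `Var_b = max(0, Var(person means) − Var_w/d̄)` with
  `Var_w` the pooled within-person variance of day-level deviations and
  `d̄` the harmonic mean of day counts (single-day persons contribute no
  within-person information; when all persons are single-day the plain
  SD of person means is used, logged). In the full chain the
  decomposition is applied to adjustment-shifted day values, which
  leaves within-person deviations untouched while centering person means
  at their energy-adjusted values;
* strata are aggregated by sampling-weighted mean; `n` is the person
  count. Design-effect/PSU-based standard errors are not implemented —
  `s/√n` is used downstream — a known limitation when complex designs
  matter;
* units convert at 1 serving = 8 fl oz = 236.588 mL, with g/day treated
  as mL/day at density 1.0; calcium passes through in mg/day.

## Synthetic worlds

The generator builds complete worlds from one seed: a strictly nested
hierarchy (default 2 super-regions / 4 regions / 12 countries, at least
2 countries per region), single-year-of-age populations, a truth surface
drawn from the model itself, partial-coverage surveys (default 60% of
countries), complete availability series, and GNI/BMI stand-in tables.
Defaults sketch an SSB-like landscape: β0 = −0.5 (≈0.6 servings/day),
intake declining with age, a +0.20 male offset, +0.15/decade time trend,
availability coefficient 0.30, several-fold regional spread
(τ_s=0.40, τ_r=0.25, τ_c=0.20), bias offsets of ±0.10–0.15 and extra
variance components of 0.10–0.15 — a landscape of the kind global
dietary surveillance reports, without using any published estimate as
truth.

Availability is generated from the *base* truth (the linear predictor
without the availability term): `value = 20 + 50·(pop-mean base intake)
+ N(0, 4)`, then z-scored, and the final truth adds `λ·z`. Generating
availability from the full truth would be circular once the truth
depends on availability; anchoring it to the base component keeps a
well-defined generating λ while availability still tracks each country's
consumption level. Survey noise is applied on the log scale with
variance equal to the model's sampling + residual + non-preferred
components, so the fitted model is exactly correctly specified and
interval-coverage checks are meaningful. That is also the main caveat:
passing recovery tests demonstrate correctness of the machinery under
the model's own assumptions, not robustness to the misspecification
(non-lognormal errors, informative survey placement, drifting bias
offsets) that real survey landscapes contain. Natural-scale noise can be
explored via the recall generator, whose person/day noise is Gaussian on
the natural scale (day values floored at 0; defaults make flooring
negligible).

## Problem sizes

The replicated checks run at desk scale, chosen to make the test suite
and the acceptance script self-contained single-CPU runs: 12-country
worlds (84 strata, 41 model parameters, 23 sampled dimensions), 20
replicates for parameter/interval recovery in the tests (12 in the
acceptance script), 8 replicates for the availability-rescue comparison,
4×20k-iteration chains for the conjugate-limit check. The full study
scope (187 countries, 21 regions, 7 super-regions, 1980–2010) runs
through the same code path; only wall-clock time grows.

## Known limitations

* One beverage per fit; no cross-beverage joint model, no spatial
  smoothing beyond the region nesting, no sex-by-age interaction.
* Bias offsets are global scalars, not region-specific crosswalks.
* The population table used for weighting is whatever the caller
  supplies; results are conditional on it.
* The corrected-SD decomposition is one standard reading of the cited
  method; a different published variant would shift `sd_intake`
  slightly.
* Chain counts and lengths are desk-scale choices made from the
  convergence diagnostics; larger worlds warrant longer runs.
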