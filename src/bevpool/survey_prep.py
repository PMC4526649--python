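"""Harmonization of per-person recall microdata into survey strata.

Implements the standard preprocessing chain for short-term dietary
instruments: averaging repeated 24-hour recalls into person means,
energy standardization by the residual method (to 2000 kcal/d), recovery
of the between-person ("corrected population") SD from the within/between
variance decomposition, and design-weighted aggregation to a
:class:`~bevpool.core_types.SurveyStratum`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_types import SurveyStratum, ValidationError

__all__ = [
    "RecallRecord",
    "TARGET_KCAL",
    "ML_PER_SERVING",
    "energy_standardize",
    "person_means",
    "corrected_sd",
    "aggregate_stratum",
    "to_servings",
    "prepare_strata",
]

log = logging.getLogger(__name__)

#: Reference energy intake for residual-method standardization, kcal/day.
TARGET_KCAL = 2000.0

#: One 8-fluid-ounce serving in millilitres.
ML_PER_SERVING = 236.588


@dataclass(frozen=True)
class RecallRecord:
    """One recall day for one person.

    ``intake`` is the day's beverage intake in servings/day equivalent;
    ``energy`` the day's total energy in kcal; ``weight`` the survey
    sampling weight (constant within person).
    """

    person_id: str
    survey_id: str
    day_index: int
    intake: float
    energy: float
    weight: float
    country_id: str
    year: int
    sex: str
    age: float

    def validate(self) -> None:
        if self.day_index < 1:
            raise ValidationError(f"day_index must be >= 1, got {self.day_index}")
        if self.intake < 0:
            raise ValidationError(f"intake must be >= 0, got {self.intake}")
        if not self.energy > 0:
            raise ValidationError(f"energy must be > 0, got {self.energy}")
        if not self.weight > 0:
            raise ValidationError(f"weight must be > 0, got {self.weight}")


def energy_standardize(
    intakes: Sequence[float],
    energies: Sequence[float],
    target_kcal: float = TARGET_KCAL,
) -> np.ndarray:
    """Residual-method energy standardization of person-level intakes.

    Fits ``intake = a + b * energy`` by least squares and returns each
    person's residual plus the fitted value at ``target_kcal``:
    ``adjusted_i = intake_i - (a + b * energy_i) + (a + b * target_kcal)``.
    With all energies identical the slope is undefined and the raw intakes
    are returned unchanged (logged).  Adjusted values are floored at zero
    (intakes are physically non-negative); the floored count is logged.
    """
    x = np.asarray(energies, dtype=float)
    y = np.asarray(intakes, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("intakes and energies must be 1-D and aligned")
    if len(y) < 3:
        raise ValidationError("insufficient data for residual method (need >= 3 persons)")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0.0:
        log.info("energy_standardize: all energies identical; returning raw intakes")
        return y.copy()
    b = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    # a cancels: adjusted = y - b*(x - target)
    adjusted = y - b * (x - target_kcal)
    n_floor = int(np.sum(adjusted < 0))
    if n_floor:
        log.info("energy_standardize: floored %d negative adjusted intakes at 0", n_floor)
        adjusted = np.maximum(adjusted, 0.0)
    return adjusted


def _person_frame(records: Iterable[RecallRecord]) -> pd.DataFrame:
    rows = [
        (
            r.person_id,
            r.survey_id,
            r.day_index,
            r.intake,
            r.energy,
            r.weight,
            r.country_id,
            r.year,
            r.sex,
            r.age,
        )
        for r in records
    ]
    if not rows:
        raise ValidationError("no recall records supplied")
    df = pd.DataFrame(
        rows,
        columns=[
            "person_id",
            "survey_id",
            "day_index",
            "intake",
            "energy",
            "weight",
            "country_id",
            "year",
            "sex",
            "age",
        ],
    )
    if df.duplicated(subset=["person_id", "day_index"]).any():
        dup = df.loc[df.duplicated(subset=["person_id", "day_index"]), "person_id"]
        raise ValidationError(f"duplicate (person, day) rows for persons {sorted(set(dup))}")
    return df


def person_means(records: Iterable[RecallRecord]) -> pd.DataFrame:
    """Average recall days into one row per person.

    Returns a frame with columns ``person_id, mean_intake, mean_energy,
    days, weight`` (weights are constant within person).
    """
    df = _person_frame(records)
    out = (
        df.groupby("person_id", sort=True)
        .agg(
            mean_intake=("intake", "mean"),
            mean_energy=("energy", "mean"),
            days=("day_index", "size"),
            weight=("weight", "first"),
        )
        .reset_index()
    )
    return out


def corrected_sd(records: Iterable[RecallRecord]) -> float:
    """Between-person SD from repeated recalls.

    The variance of observed person means overstates the between-person
    variance by the within-person variance divided by the number of recall
    days.  Decompose:

    * ``var_within`` — pooled variance of day-level deviations from each
      person's own mean (persons with a single day contribute nothing);
    * ``var_between = max(0, var(person means) - var_within / d̄)`` with
      ``d̄`` the harmonic mean of per-person day counts.

    Returns ``sqrt(var_between)``.  When every person has a single day the
    correction is impossible and the plain SD of person means is returned
    (logged).
    """
    df = _person_frame(records)
    g = df.groupby("person_id", sort=True)["intake"]
    means = g.mean()
    days = g.size()
    if len(means) < 2:
        raise ValidationError("corrected_sd requires >= 2 persons")
    var_means = float(means.var(ddof=1))
    if (days == 1).all():
        log.info("corrected_sd: all persons single-day; returning plain SD of means")
        return float(np.sqrt(var_means))
    dev_sq = (df["intake"] - df["person_id"].map(means)) ** 2
    denom = int((days - 1).sum())
    var_within = float(dev_sq.sum() / denom)
    d_bar = len(days) / float((1.0 / days).sum())  # harmonic mean of day counts
    var_between = max(0.0, var_means - var_within / d_bar)
    return float(np.sqrt(var_between))


def aggregate_stratum(
    persons: pd.DataFrame,
    *,
    country_id: str,
    year: int,
    sex: str,
    age_lo: int,
    age_hi: int,
    survey_id: str = "",
    nationally_representative: bool = True,
    individual_level: bool = True,
    primary_metric: bool = True,
    optimal_assessment: bool = True,
    sd_override: float | None = None,
    unit: str = "servings/day",
) -> SurveyStratum:
    """Design-weighted aggregation of person means into one stratum.

    ``persons`` needs columns ``mean_intake`` and ``weight``.  The stratum
    mean is the weighted mean; the SD is ``sd_override`` when a corrected
    SD is available from repeated recalls, else the weighted population SD
    of person means; ``n`` is the person count.
    """
    if len(persons) < 1:
        raise ValidationError("aggregate_stratum requires >= 1 person")
    w = persons["weight"].to_numpy(dtype=float)
    x = persons["mean_intake"].to_numpy(dtype=float)
    total = w.sum()
    if not total > 0:
        raise ValidationError("zero total weight in stratum")
    mean = float(np.sum(w * x) / total)
    if sd_override is not None:
        sd = float(sd_override)
    else:
        sd = float(np.sqrt(np.sum(w * (x - mean) ** 2) / total))
    stratum = SurveyStratum(
        country_id=country_id,
        year=year,
        sex=sex,
        age_lo=age_lo,
        age_hi=age_hi,
        mean_intake=mean,
        sd_intake=sd,
        n=len(persons),
        nationally_representative=nationally_representative,
        individual_level=individual_level,
        primary_metric=primary_metric,
        optimal_assessment=optimal_assessment,
        survey_id=survey_id,
        unit=unit,
    )
    stratum.validate()
    return stratum


_UNIT_FACTORS = {
    "servings/day": 1.0,
    "mL/day": 1.0 / ML_PER_SERVING,
    "g/day": 1.0 / ML_PER_SERVING,  # density 1.0 g/mL assumed
    "oz/day": 1.0 / 8.0,
}


def to_servings(value: float, unit: str, beverage: str = "ssb") -> float:
    """Convert a declared-unit intake to 8-oz servings/day.

    One serving is 8 fluid ounces (236.588 mL); gram amounts are treated
    as millilitres at density 1.0 g/mL.  Calcium is a nutrient, not a
    volume, and passes through in mg/day.
    """
    if beverage == "calcium":
        if unit != "mg/day":
            raise ValidationError("calcium intake must be declared in mg/day")
        return float(value)
    try:
        return float(value) * _UNIT_FACTORS[unit]
    except KeyError:
        raise ValidationError(
            f"unknown unit {unit!r}; accepted units: {sorted(_UNIT_FACTORS)}"
        ) from None


def prepare_strata(
    records: Iterable[RecallRecord],
    *,
    target_kcal: float = TARGET_KCAL,
    age_bands: Sequence[tuple[int, int]] = ((20, 100),),
    flags: dict | None = None,
) -> list[SurveyStratum]:
    """Full preprocessing chain: recalls -> harmonized strata.

    Groups records by (country, year, sex, age band, survey), averages
    recall days per person, energy-standardizes the person means, and
    aggregates.  The stratum SD applies the within/between correction to
    the *adjusted* person means: each person's day values are shifted by
    their adjustment delta (which leaves within-person deviations intact)
    before the variance decomposition.  Strata with fewer than 3 persons
    skip energy standardization (logged).
    """
    flags = flags or {}
    df = _person_frame(records)
    bands = list(age_bands)

    def band_of(age: float):
        for lo, hi in bands:
            if lo <= age < hi:
                return (lo, hi)
        return None

    df["band"] = df["age"].map(band_of)
    df = df[df["band"].notna()]
    strata: list[SurveyStratum] = []
    for (country, year, sex, band, survey), sub in df.groupby(
        ["country_id", "year", "sex", "band", "survey_id"], sort=True
    ):
        sub_records = [
            RecallRecord(
                person_id=r.person_id,
                survey_id=r.survey_id,
                day_index=r.day_index,
                intake=r.intake,
                energy=r.energy,
                weight=r.weight,
                country_id=r.country_id,
                year=r.year,
                sex=r.sex,
                age=r.age,
            )
            for r in sub.itertuples(index=False)
        ]
        persons = person_means(sub_records)
        if len(persons) >= 3:
            adjusted = energy_standardize(
                persons["mean_intake"], persons["mean_energy"], target_kcal
            )
        else:
            log.info(
                "prepare_strata: stratum %s has < 3 persons; skipping energy standardization",
                (country, year, sex, band, survey),
            )
            adjusted = persons["mean_intake"].to_numpy(dtype=float)
        delta = adjusted - persons["mean_intake"].to_numpy(dtype=float)
        shift = dict(zip(persons["person_id"], delta))
        multi_day = (persons["days"] > 1).any()
        sd = None
        if multi_day and len(persons) >= 2:
            shifted = [
                replace(r, intake=max(0.0, r.intake + shift[r.person_id]))
                for r in sub_records
            ]
            sd = corrected_sd(shifted)
        persons_adj = persons.assign(mean_intake=adjusted)
        strata.append(
            aggregate_stratum(
                persons_adj,
                country_id=country,
                year=int(year),
                sex=sex,
                age_lo=int(band[0]),
                age_hi=int(band[1]),
                survey_id=survey,
                sd_override=sd,
                **flags,
            )
        )
    return strata
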