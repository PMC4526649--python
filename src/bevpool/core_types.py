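"""Shared data model, region hierarchy, and validated tabular I/O.

Every table crossing the package boundary is CSV (UTF-8, header row, dot
decimal).  The harmonized observation unit is :class:`SurveyStratum` — one
country-year-sex-age-range mean intake with its SD, sample size and four
data-quality flags.  Countries nest in regions nest in super-regions
(:class:`RegionHierarchy`); at full global scope that is 187 countries,
21 regions and 7 super-regions, but any strictly nested three-level world
is accepted.  Income classes follow the World Bank Atlas thresholds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "SurveyStratum",
    "AvailabilityRecord",
    "PopulationCell",
    "IncomeClass",
    "RegionHierarchy",
    "HierarchyReport",
    "validate_hierarchy",
    "classify_income",
    "read_strata",
    "write_strata",
    "read_availability",
    "write_availability",
    "read_population",
    "write_population",
    "read_hierarchy",
    "write_hierarchy",
    "OPEN_ENDED_AGE",
]

#: Upper bound used to close the open-ended top age band ("80+" -> [80, 100)).
OPEN_ENDED_AGE = 100

SEXES = ("female", "male")

BEVERAGES = ("ssb", "fruit_juice", "milk", "calcium")


class SchemaError(ValueError):
    """A required column is missing or a table header is malformed."""


class ValidationError(ValueError):
    """A row or value violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurveyStratum:
    """One harmonized survey observation: the model's likelihood unit.

    ``mean_intake`` and ``sd_intake`` are in 8-oz servings/day (mg/day for
    calcium).  The four boolean flags are *preferred-positive*: ``True``
    means the observation has the preferred characteristic (nationally
    representative, individual-level, primary metric, optimal assessment).
    """

    country_id: str
    year: int
    sex: str
    age_lo: int
    age_hi: int
    mean_intake: float
    sd_intake: float
    n: int
    nationally_representative: bool = True
    individual_level: bool = True
    primary_metric: bool = True
    optimal_assessment: bool = True
    survey_id: str = ""
    unit: str = "servings/day"

    def validate(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.mean_intake < 0:
            raise ValidationError(f"mean_intake must be >= 0, got {self.mean_intake}")
        if self.sd_intake < 0:
            raise ValidationError(f"sd_intake must be >= 0, got {self.sd_intake}")
        if self.n < 1:
            raise ValidationError(f"n must be >= 1, got {self.n}")
        if self.age_lo < 20:
            raise ValidationError(
                f"age_lo must be >= 20 (adults-only scope), got {self.age_lo}"
            )
        if not self.age_lo < self.age_hi:
            raise ValidationError(
                f"age_lo must be < age_hi, got [{self.age_lo}, {self.age_hi}]"
            )


@dataclass(frozen=True)
class AvailabilityRecord:
    """Country-year per-capita availability of one beverage proxy.

    National food-balance availability (total sugar for SSBs, total fruit
    for juice, milk directly) is the model's time-varying country covariate;
    ``z_value`` holds the standardized version filled in by the model.
    """

    country_id: str
    year: int
    beverage: str
    value: float
    z_value: float | None = None

    def validate(self) -> None:
        if self.beverage not in BEVERAGES:
            raise ValidationError(f"beverage must be one of {BEVERAGES}")
        if self.value < 0:
            raise ValidationError(f"availability value must be >= 0, got {self.value}")


@dataclass(frozen=True)
class PopulationCell:
    """Person count for one country-year-sex-age cell (single year of age)."""

    country_id: str
    year: int
    sex: str
    age: int
    count: float

    def validate(self) -> None:
        if self.count < 0:
            raise ValidationError(f"population count must be >= 0, got {self.count}")


@dataclass(frozen=True)
class IncomeClass:
    country_id: str
    gni_per_capita: float
    income_class: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "income_class", classify_income(self.gni_per_capita))


def classify_income(gni_per_capita: float) -> str:
    """World Bank Atlas income class from per-capita GNI in 2013 US dollars.

    ``<= 1045`` is low income; ``>= 12746`` is high income; the middle band
    splits at 4125 into lower-middle (``<= 4125``) and upper-middle.
    """
    if not gni_per_capita > 0:
        raise ValidationError(f"GNI per capita must be positive, got {gni_per_capita}")
    if gni_per_capita <= 1045:
        return "low"
    if gni_per_capita <= 4125:
        return "lower_middle"
    if gni_per_capita < 12746:
        return "upper_middle"
    return "high"


# ---------------------------------------------------------------------------
# Region hierarchy
# ---------------------------------------------------------------------------


@dataclass
class HierarchyReport:
    n_countries: int
    n_regions: int
    n_super_regions: int
    orphan_countries: list[str]

    @property
    def level_counts(self) -> tuple[int, int, int]:
        return (self.n_countries, self.n_regions, self.n_super_regions)


class RegionHierarchy:
    """Three-level nesting of countries in regions in super-regions.

    Wraps a frame with columns ``country_id, region_id, super_region_id``
    and provides the lookups that drive random-effect nesting and
    population-weighted aggregation.
    """

    COLUMNS = ("country_id", "region_id", "super_region_id")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"hierarchy table missing columns: {missing}")
        self.frame = frame.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        validate_hierarchy(self.frame)
        self.countries: list[str] = sorted(self.frame["country_id"])
        self.regions: list[str] = sorted(self.frame["region_id"].unique())
        self.super_regions: list[str] = sorted(self.frame["super_region_id"].unique())
        self._region_of = dict(zip(self.frame["country_id"], self.frame["region_id"]))
        self._super_of_region = dict(
            zip(self.frame["region_id"], self.frame["super_region_id"])
        )

    def region_of(self, country_id: str) -> str:
        try:
            return self._region_of[country_id]
        except KeyError:
            raise ValidationError(f"unknown country {country_id!r}") from None

    def super_region_of(self, country_id: str) -> str:
        return self._super_of_region[self.region_of(country_id)]

    def __contains__(self, country_id: str) -> bool:
        return country_id in self._region_of

    def __len__(self) -> int:
        return len(self.countries)


def validate_hierarchy(hierarchy: pd.DataFrame | RegionHierarchy) -> HierarchyReport:
    """Check strict nesting and report level counts and orphan rows.

    A country mapped to two regions, or a region mapped to two
    super-regions, breaks the nesting and raises :class:`ValidationError`.
    Rows with missing labels are reported as orphans.
    """
    frame = hierarchy.frame if isinstance(hierarchy, RegionHierarchy) else hierarchy
    if len(frame) == 0:
        raise ValidationError("hierarchy table is empty")
    missing = [c for c in RegionHierarchy.COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"hierarchy table missing columns: {missing}")

    orphan_mask = frame[list(RegionHierarchy.COLUMNS)].isna().any(axis=1)
    orphans = sorted(frame.loc[orphan_mask, "country_id"].dropna().astype(str))
    clean = frame.loc[~orphan_mask]

    dup_country = clean.groupby("country_id")["region_id"].nunique()
    bad = dup_country[dup_country > 1]
    if len(bad):
        raise ValidationError(
            f"countries mapped to multiple regions: {sorted(bad.index)}"
        )
    if clean["country_id"].duplicated().any():
        dups = sorted(clean.loc[clean["country_id"].duplicated(), "country_id"])
        raise ValidationError(f"duplicated country rows: {dups}")
    dup_region = clean.groupby("region_id")["super_region_id"].nunique()
    bad_r = dup_region[dup_region > 1]
    if len(bad_r):
        raise ValidationError(
            f"regions mapped to multiple super-regions: {sorted(bad_r.index)}"
        )

    return HierarchyReport(
        n_countries=clean["country_id"].nunique(),
        n_regions=clean["region_id"].nunique(),
        n_super_regions=clean["super_region_id"].nunique(),
        orphan_countries=orphans,
    )


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

_STRATA_COLUMNS = [
    "country_id",
    "year",
    "sex",
    "age_lo",
    "age_hi",
    "mean_intake",
    "sd_intake",
    "n",
    "nationally_representative",
    "individual_level",
    "primary_metric",
    "optimal_assessment",
    "survey_id",
    "unit",
]

_VALID_UNITS = ("servings/day", "mg/day")


def _parse_age_hi(raw) -> int:
    # "80+" encodes the open-ended top band; closed at OPEN_ENDED_AGE.
    s = str(raw).strip()
    if s.endswith("+"):
        return OPEN_ENDED_AGE
    return int(float(s))


def read_strata(path: str | Path) -> list[SurveyStratum]:
    """Read and validate a survey-strata CSV.

    Rows violating domain invariants are rejected with row-numbered
    diagnostics; a missing required column raises :class:`SchemaError`.
    """
    df = pd.read_csv(path, dtype={"survey_id": str})
    missing = [c for c in _STRATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"strata file {path}: missing required columns {missing}")
    strata: list[SurveyStratum] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            unit = str(row.unit).strip()
            if unit not in _VALID_UNITS:
                raise ValidationError(
                    f"unit must be one of {_VALID_UNITS}, got {unit!r}"
                )
            s = SurveyStratum(
                country_id=str(row.country_id),
                year=int(row.year),
                sex=str(row.sex),
                age_lo=int(row.age_lo),
                age_hi=_parse_age_hi(row.age_hi),
                mean_intake=float(row.mean_intake),
                sd_intake=float(row.sd_intake),
                n=int(row.n),
                nationally_representative=bool(int(row.nationally_representative)),
                individual_level=bool(int(row.individual_level)),
                primary_metric=bool(int(row.primary_metric)),
                optimal_assessment=bool(int(row.optimal_assessment)),
                survey_id=str(row.survey_id),
                unit=unit,
            )
            s.validate()
            strata.append(s)
        except (ValueError, ValidationError) as exc:
            errors.append(f"line {i}: {exc}")
    if errors:
        raise ValidationError(
            "invalid strata rows:\n" + "\n".join(errors)
        )
    return strata


def write_strata(strata: Iterable[SurveyStratum], path: str | Path) -> None:
    rows = []
    for s in strata:
        d = dataclasses.asdict(s)
        for flag in (
            "nationally_representative",
            "individual_level",
            "primary_metric",
            "optimal_assessment",
        ):
            d[flag] = int(d[flag])
        rows.append(d)
    pd.DataFrame(rows, columns=_STRATA_COLUMNS).to_csv(path, index=False)


def _read_table(path, required: Sequence[str], label: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{label} file {path}: missing required columns {missing}")
    return df


def read_availability(path: str | Path) -> pd.DataFrame:
    """Availability series as a frame (country_id, year, beverage, value)."""
    df = _read_table(path, ["country_id", "year", "beverage", "value"], "availability")
    if (df["value"] < 0).any():
        bad = df.index[df["value"] < 0] + 2
        raise ValidationError(f"negative availability values at lines {list(bad)}")
    return df


def write_availability(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_population(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, ["country_id", "year", "sex", "age", "count"], "population")
    if (df["count"] < 0).any():
        bad = df.index[df["count"] < 0] + 2
        raise ValidationError(f"negative population counts at lines {list(bad)}")
    return df


def write_population(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_hierarchy(path: str | Path) -> RegionHierarchy:
    return RegionHierarchy(
        _read_table(path, RegionHierarchy.COLUMNS, "hierarchy")
    )


def write_hierarchy(hierarchy: RegionHierarchy, path: str | Path) -> None:
    hierarchy.frame.to_csv(path, index=False)


def load_reference_hierarchy() -> RegionHierarchy:
    """The world-region membership table shipped with the package.

    Transcribed from the published region listing (ISO-3166 alpha-3 codes
    added); the four Sub-Saharan and five Latin-American sub-regions nest
    in their continental groupings, high-income North America and
    Australasia stand alone.
    """
    path = Path(__file__).parent / "data" / "region_hierarchy.csv"
    return RegionHierarchy(pd.read_csv(path))
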