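"""From posterior parameter draws to the reporting surface.

All downstream quantities are carried as aligned draw vectors: draw *j*
of every cell comes from posterior parameter draw *j*, so population-
weighted aggregates, 1990→2010 differences and their uncertainty
intervals propagate the full correlation structure.  Point estimates are
draw means; 95% uncertainty intervals are the 2.5th and 97.5th
percentiles of the draws (linear interpolation between order statistics).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_types import ValidationError
from .exposure_model import ParameterSpace

__all__ = [
    "Cell",
    "ExposureDraws",
    "ExposureEstimate",
    "DiffResult",
    "cell_draws",
    "summarize",
    "aggregate_draws",
    "diff_draws",
    "correlate_exposures",
    "band_population",
]

#: Number of posterior draws carried through all summaries.
N_DRAWS = 1000

UI_PERCENTILES = (2.5, 97.5)


class Cell(NamedTuple):
    """One reporting cell: country-year-sex-age band."""

    country_id: str
    year: int
    sex: str
    age_lo: int
    age_hi: int


@dataclass
class ExposureDraws:
    cell: Cell
    draws: np.ndarray

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)


@dataclass
class ExposureEstimate:
    cell: Cell
    mean: float
    ui_lo: float
    ui_hi: float


@dataclass
class DiffResult:
    """Draw-level contrast between two cells (e.g. 2010 minus 1990)."""

    absolute: ExposureEstimate
    relative: ExposureEstimate
    significant: bool  # absolute-difference 95% UI excludes 0


def cell_draws(
    param_draws: np.ndarray,
    cell: Cell,
    z_avail: float | Mapping[tuple[str, int], float],
    space: ParameterSpace,
    pop_weights: Mapping[int, float] | None = None,
) -> ExposureDraws:
    """Exposure draws for one cell from posterior parameter draws.

    Each parameter draw is pushed through ``exp(linear predictor)`` with
    all four bias flags at their preferred level, so estimates are
    debiased to the national / individual-level / primary-metric /
    optimal-assessment standard.  ``z_avail`` is either the cell's
    standardized availability or a (country, year) lookup.
    """
    if isinstance(z_avail, Mapping):
        key = (cell.country_id, cell.year)
        if key not in z_avail:
            raise ValidationError(f"availability missing for {key}")
        z = float(z_avail[key])
    else:
        z = float(z_avail)
    row = space.design_row(
        country_id=cell.country_id,
        year=cell.year,
        sex=cell.sex,
        age_lo=cell.age_lo,
        age_hi=cell.age_hi,
        z_avail=z,
        flags=(0.0, 0.0, 0.0, 0.0),
        pop_weights=pop_weights,
    )
    draws = np.exp(np.asarray(param_draws)[:, : space.n_linear] @ row)
    return ExposureDraws(cell=cell, draws=draws)


def summarize(draws: ExposureDraws | np.ndarray, cell: Cell | None = None) -> ExposureEstimate:
    """Mean and 95% UI (2.5th/97.5th percentiles) of a draw vector."""
    if isinstance(draws, ExposureDraws):
        cell = draws.cell
        values = draws.draws
    else:
        values = np.asarray(draws, dtype=float)
    if values.size < 2:
        raise ValidationError("summarize requires >= 2 draws")
    lo, hi = np.percentile(values, UI_PERCENTILES, method="linear")
    return ExposureEstimate(cell=cell, mean=float(values.mean()), ui_lo=float(lo), ui_hi=float(hi))


def aggregate_draws(
    members: Sequence[ExposureDraws],
    weights: Sequence[float] | Mapping[Cell, float],
    cell: Cell | None = None,
) -> ExposureDraws:
    """Population-weighted mean of member cells, computed per draw index.

    Aggregating at the draw level (rather than on summaries) keeps the
    parameter-induced correlation between cells inside the aggregate's
    uncertainty interval.
    """
    if not members:
        raise ValidationError("aggregate_draws needs at least one member cell")
    if isinstance(weights, Mapping):
        w = []
        for m in members:
            if m.cell not in weights:
                raise ValidationError(f"weight missing for cell {m.cell}")
            w.append(float(weights[m.cell]))
        w = np.asarray(w)
    else:
        w = np.asarray(list(weights), dtype=float)
        if len(w) != len(members):
            raise ValidationError("weights must align with member cells")
    n = members[0].draws.size
    if any(m.draws.size != n for m in members):
        raise ValidationError("member cells have mismatched draw counts")
    total = w.sum()
    if not total > 0:
        raise ValidationError("aggregate weights sum to zero")
    stacked = np.stack([m.draws for m in members])
    agg = (w / total) @ stacked
    return ExposureDraws(cell=cell if cell is not None else members[0].cell, draws=agg)


def diff_draws(draws_a: ExposureDraws, draws_b: ExposureDraws) -> DiffResult:
    """Draw-level absolute and relative difference (b minus a).

    The change is computed within each draw before summarizing, so the
    uncertainty of the difference accounts for the correlation between
    the two periods.  The contrast is flagged non-significant when the
    95% UI of the absolute difference contains 0.
    """
    a, b = draws_a.draws, draws_b.draws
    if a.size != b.size:
        raise ValidationError("mismatched draw counts")
    absolute = b - a
    with np.errstate(divide="ignore", invalid="ignore"):
        relative = np.where(a != 0, absolute / a, np.nan)
    cell = draws_b.cell
    abs_est = summarize(absolute, cell)
    rel_est = summarize(relative, cell)
    significant = not (abs_est.ui_lo <= 0.0 <= abs_est.ui_hi)
    return DiffResult(absolute=abs_est, relative=rel_est, significant=significant)


def correlate_exposures(
    x: pd.DataFrame,
    y: pd.DataFrame,
    by: Sequence[str] = ("sex", "age_lo", "age_hi"),
) -> pd.DataFrame:
    """Cross-country Pearson correlation of two exposures, per stratum.

    ``x`` and ``y`` are frames of posterior-mean estimates with columns
    ``country_id``, the stratum keys in ``by``, and ``mean``.  Within each
    stratum the country-level means are paired and correlated.  Strata
    with fewer than 3 paired countries or zero variance yield ``NaN``.
    """
    by = list(by)
    merged = x.merge(y, on=["country_id", *by], suffixes=("_x", "_y"))
    rows = []
    for key, sub in merged.groupby(by, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        vx = sub["mean_x"].to_numpy(dtype=float)
        vy = sub["mean_y"].to_numpy(dtype=float)
        if len(sub) < 3 or vx.std() == 0 or vy.std() == 0:
            r = np.nan
        else:
            r = float(stats.pearsonr(vx, vy).statistic)
        rows.append(dict(zip(by, key)) | {"r": r, "n_countries": len(sub)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Population weight helpers
# ---------------------------------------------------------------------------


def band_population(populations: pd.DataFrame, cell: Cell) -> float:
    """Total population of one country-year-sex-age-band cell."""
    mask = (
        (populations["country_id"] == cell.country_id)
        & (populations["year"] == cell.year)
        & (populations["sex"] == cell.sex)
        & (populations["age"] >= cell.age_lo)
        & (populations["age"] < cell.age_hi)
    )
    return float(populations.loc[mask, "count"].sum())
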