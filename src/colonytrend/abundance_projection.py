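"""Interpolation and projection of colony abundances along fitted trajectories.

Abundance at a target year is evaluated on the colony's exponential
trajectory anchored at an *observed* census:

* target year equal to a census year -> the observed count itself;
* target year inside or after the observed span -> N_anchor *
  lambda**(year - t_anchor), where the anchor is the latest census at or
  before the target year;
* target year before the first census -> excluded (no backward
  extrapolation; colonies first recorded after a reference year would
  otherwise be assigned unsupported historical abundances).

For colonies that went through an explosive establishment phase (El Pedral
and Estancia San Lorenzo in the reference dataset), a whole-series fit
wildly over-projects; their lambda is recomputed from the most recent
records only (default: last 3) and used for recent reference years and the
forward projection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .colony_data import ColonySeries
from .errors import AlignmentError, DegenerateInputError, UndefinedRateError
from .trend_estimation import (
    TrendEstimate,
    fit_log_linear,
    fit_two_point,
)
from dataclasses import replace as _replace

OBSERVED = "observed"
INTERPOLATED = "interpolated"
PROJECTED = "projected"
EXCLUDED_BACKWARD = "excluded_backward"

TWO_RECORD = "two_record"
THREE_PLUS = "three_plus_record"


@dataclass(frozen=True)
class ProjectionConfig:
    """Reference years, projection year and recent-phase adjustments."""

    reference_years: tuple[int, ...] = (1996, 2006, 2016)
    projection_year: int = 2024
    recent_lambda_colonies: tuple[str, ...] = ("EP", "ESL")
    recent_window: int = 3
    recent_from_year: int = 2016
    allow_backward: bool = False
    malvinas_id: str = "IM"

    def __post_init__(self) -> None:
        if self.reference_years and self.projection_year < max(self.reference_years):
            raise ValueError("projection_year must be >= every reference year")
        if self.recent_window < 2:
            raise ValueError("recent_window must be >= 2")

    @property
    def target_years(self) -> tuple[int, ...]:
        return tuple(sorted({*self.reference_years, self.projection_year}))


@dataclass(frozen=True)
class AbundanceTable:
    """Per-colony abundances for one target year plus stratum/national totals.

    ``entries`` columns: colony_id, abundance, status, stratum.  Colonies
    excluded by the backward guard appear with abundance 0 and status
    ``excluded_backward`` — flagged, never silently dropped.
    """

    target_year: int
    entries: pd.DataFrame
    malvinas_id: str = "IM"

    def _included(self, exclude_malvinas: bool = False) -> pd.DataFrame:
        df = self.entries[self.entries["status"] != EXCLUDED_BACKWARD]
        if exclude_malvinas:
            df = df[df["colony_id"] != self.malvinas_id]
        return df

    def national_total(self, *, exclude_malvinas: bool = False) -> float:
        return float(self._included(exclude_malvinas)["abundance"].sum())

    def group_totals(self, *, exclude_malvinas: bool = False) -> dict[str, float]:
        df = self._included(exclude_malvinas)
        return {
            stratum: float(df.loc[df["stratum"] == stratum, "abundance"].sum())
            for stratum in (TWO_RECORD, THREE_PLUS)
        }


def interpolate_to_year(
    series: ColonySeries,
    estimate: TrendEstimate,
    year: int,
    *,
    allow_backward: bool = False,
) -> tuple[Optional[float], str]:
    """Evaluate the colony trajectory at ``year``.

    Returns ``(abundance, status)``; abundance is ``None`` with status
    ``excluded_backward`` when the year precedes the first census and
    backward extrapolation is disabled.
    """
    if estimate.colony_id != series.colony_id:
        raise AlignmentError(
            f"estimate for {estimate.colony_id} applied to series {series.colony_id}"
        )
    if year < series.first_year:
        if not allow_backward:
            return None, EXCLUDED_BACKWARD
        anchor = series.records[0]
        value = anchor.breeding_pairs * estimate.lam ** (year - anchor.season_year)
        return float(value), INTERPOLATED
    for rec in series.records:
        if rec.season_year == year:
            return float(rec.breeding_pairs), OBSERVED
    # latest census at or before the target year
    anchor = max(
        (rec for rec in series.records if rec.season_year <= year),
        key=lambda rec: rec.season_year,
    )
    value = float(anchor.breeding_pairs * estimate.lam ** (year - anchor.season_year))
    status = PROJECTED if year > series.last_year else INTERPOLATED
    return value, status


def project_to_year(series: ColonySeries, estimate: TrendEstimate, year: int) -> float:
    """Project forward from the most recent census: N_last * lambda**(dt)."""
    if year < series.last_year:
        raise DegenerateInputError(
            f"colony {series.colony_id}: {year} precedes the last census "
            f"({series.last_year}); use interpolate_to_year"
        )
    value, _ = interpolate_to_year(series, estimate, year)
    assert value is not None
    return value


def recompute_recent_lambda(series: ColonySeries, window: int) -> TrendEstimate:
    """Refit the trend on the most recent ``window`` records only.

    Two-point fit when the window is 2, log-linear otherwise.  The estimate
    is flagged ``recent_phase`` so reports can tell it apart from the
    whole-series fit.
    """
    if window < 2:
        raise DegenerateInputError("recent window must be >= 2")
    if window > series.n_records:
        raise DegenerateInputError(
            f"colony {series.colony_id}: recent window {window} exceeds "
            f"{series.n_records} records"
        )
    recent = ColonySeries(
        colony_id=series.colony_id,
        records=series.records[-window:],
        name=series.name,
        latitude=series.latitude,
        longitude=series.longitude,
        region=series.region,
    )
    est = fit_two_point(recent) if window == 2 else fit_log_linear(recent)
    return _replace(est, recent_phase=True)


def percent_change(before: float, after: float) -> float:
    """Signed percent change 100 * (after - before) / before."""
    if before <= 0:
        raise UndefinedRateError(f"percent change undefined for baseline {before}")
    return 100.0 * (after - before) / before


def _trend_map(
    trends: Iterable[TrendEstimate] | Mapping[str, TrendEstimate],
) -> dict[str, TrendEstimate]:
    if isinstance(trends, Mapping):
        return dict(trends)
    return {t.colony_id: t for t in trends}


def national_summary(
    series: Sequence[ColonySeries],
    trends: Iterable[TrendEstimate] | Mapping[str, TrendEstimate],
    config: ProjectionConfig = ProjectionConfig(),
) -> dict[int, AbundanceTable]:
    """Per-year abundance tables with stratum and national totals.

    Single-record colonies are outside the trend analysis and are ignored.
    Every colony with >= 2 records must have a trend.  Recent-phase lambdas
    (per ``config``) replace the whole-series fit for target years at or
    after ``config.recent_from_year``.
    """
    usable = [s for s in series if s.n_records >= 2]
    tmap = _trend_map(trends)
    missing = sorted({s.colony_id for s in usable} - set(tmap))
    if missing:
        raise AlignmentError(f"no trend estimate for colonies: {missing}")

    recent: dict[str, TrendEstimate] = {}
    for ser in usable:
        if (
            ser.colony_id in config.recent_lambda_colonies
            and ser.n_records >= config.recent_window
        ):
            recent[ser.colony_id] = recompute_recent_lambda(ser, config.recent_window)

    tables: dict[int, AbundanceTable] = {}
    for year in config.target_years:
        rows = []
        for ser in usable:
            est = tmap[ser.colony_id]
            if ser.colony_id in recent and year >= config.recent_from_year:
                est = recent[ser.colony_id]
            value, status = interpolate_to_year(
                ser, est, year, allow_backward=config.allow_backward
            )
            rows.append(
                {
                    "colony_id": ser.colony_id,
                    "abundance": 0.0 if value is None else value,
                    "status": status,
                    "stratum": TWO_RECORD if ser.n_records == 2 else THREE_PLUS,
                }
            )
        tables[year] = AbundanceTable(
            target_year=year,
            entries=pd.DataFrame(rows),
            malvinas_id=config.malvinas_id,
        )
    return tables
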