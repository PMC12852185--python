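"""Colony census data model, CSV I/O and the bundled colony-trend table.

The analysis unit is a *colony*: a discrete breeding aggregation of
Magellanic penguins (*Spheniscus magellanicus*), censused in breeding pairs
(active nests).  A colony's history is a short, usually irregular series of
``(season_year, breeding_pairs)`` records.  Breeding seasons span two
calendar years (September-February); a season such as 1989-1990 is keyed to
its first calendar year (1989) throughout the package.

The module also ships a machine-readable transcription of the published
per-colony trend table (65 colonies along the Argentine coast plus the
Malvinas/Falklands unit): identifiers, coordinates, province, instantaneous
growth rate r, finite growth rate lambda, 95% confidence limits where a
colony had enough census years, and the significance flag.  The underlying
census series themselves were never deposited, so this table is the
package's reference object for consistency checks.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

#: Sanity bounds on census years for this monitoring domain.
YEAR_BOUNDS = (1950, 2030)

#: Provinces / administrative units a colony can belong to.
REGIONS = ("Río Negro", "Chubut", "Santa Cruz", "Tierra del Fuego", "Malvinas")

#: Required columns of a census CSV (``source`` is optional).
CENSUS_COLUMNS = ("colony_id", "season_year", "breeding_pairs")

_FIXTURE_NAME = "published_trends.csv"


@dataclass(frozen=True)
class CensusRecord:
    """One census: breeding pairs counted at a colony in one breeding season."""

    colony_id: str
    season_year: int
    breeding_pairs: float
    source: str = ""

    def __post_init__(self) -> None:
        if not self.colony_id:
            raise ValidationError("colony_id must be a non-empty string")
        if not math.isfinite(self.breeding_pairs) or self.breeding_pairs < 0:
            raise ValidationError(
                f"breeding_pairs must be finite and >= 0, got {self.breeding_pairs!r} "
                f"for colony {self.colony_id} in {self.season_year}"
            )
        lo, hi = YEAR_BOUNDS
        if not lo <= self.season_year <= hi:
            raise ValidationError(
                f"season_year {self.season_year} outside sanity bounds {YEAR_BOUNDS} "
                f"for colony {self.colony_id}"
            )


@dataclass(frozen=True)
class ColonySeries:
    """A colony's metadata plus its ordered census records.

    Records are sorted by season year, strictly increasing: one count per
    season, duplicates rejected.  The first record anchors the colony's
    ``N_0`` and ``t_0`` and guards backward interpolation.
    """

    colony_id: str
    records: tuple[CensusRecord, ...]
    name: str = ""
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    region: Optional[str] = None

    def __post_init__(self) -> None:
        records = tuple(self.records)
        object.__setattr__(self, "records", records)
        if not records:
            raise ValidationError(f"colony {self.colony_id}: needs at least one record")
        for rec in records:
            if rec.colony_id != self.colony_id:
                raise ValidationError(
                    f"record for colony {rec.colony_id!r} attached to series "
                    f"{self.colony_id!r}"
                )
        years = [rec.season_year for rec in records]
        for prev, nxt in zip(years, years[1:]):
            if nxt == prev:
                raise ValidationError(
                    f"colony {self.colony_id}: duplicate record for season year {prev}"
                )
            if nxt < prev:
                raise ValidationError(
                    f"colony {self.colony_id}: records must be sorted by season year"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def years(self) -> np.ndarray:
        return np.array([rec.season_year for rec in self.records], dtype=float)

    @property
    def counts(self) -> np.ndarray:
        return np.array([rec.breeding_pairs for rec in self.records], dtype=float)

    @property
    def first_year(self) -> int:
        return self.records[0].season_year

    @property
    def last_year(self) -> int:
        return self.records[-1].season_year

    @property
    def span_years(self) -> int:
        return self.last_year - self.first_year


@dataclass(frozen=True)
class PublishedTrendRow:
    """One row of the bundled published trend table (65 colonies)."""

    row_number: int
    colony_id: str
    name: str
    latitude: float
    longitude: float
    region: str
    printed_r: float
    printed_lambda: float
    printed_ci: Optional[tuple[float, float]]
    significant: bool

    def __post_init__(self) -> None:
        if self.printed_lambda <= 0:
            raise ValidationError(
                f"row {self.row_number}: printed lambda must be positive"
            )


# ---------------------------------------------------------------------------
# census CSV I/O
# ---------------------------------------------------------------------------


def read_census(path: str | Path) -> list[ColonySeries]:
    """Read a long-format census CSV into one :class:`ColonySeries` per colony.

    Expected schema: ``colony_id,season_year,breeding_pairs[,source]``
    (comma-separated, UTF-8, header row, ``.`` decimal separator).  Series
    are returned in order of first appearance; records are sorted by year
    within each colony.  All malformed rows are reported together, with
    their file line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in CENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {', '.join(missing)}; "
            f"found columns {list(df.columns)}"
        )
    has_source = "source" in df.columns

    problems: list[str] = []
    seen: dict[tuple[str, int], int] = {}
    grouped: dict[str, list[CensusRecord]] = {}
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2  # header is line 1
        cid = str(getattr(row, "colony_id")).strip()
        try:
            year = int(str(getattr(row, "season_year")).strip())
        except ValueError:
            problems.append(f"line {line}: season_year {getattr(row, 'season_year')!r} is not an integer")
            continue
        try:
            pairs = float(str(getattr(row, "breeding_pairs")).strip())
        except ValueError:
            problems.append(f"line {line}: breeding_pairs {getattr(row, 'breeding_pairs')!r} is not a number")
            continue
        source = str(getattr(row, "source")) if has_source else ""
        key = (cid, year)
        if key in seen:
            problems.append(
                f"duplicate record for colony {cid} year {year} "
                f"(lines {seen[key]} and {line})"
            )
            continue
        seen[key] = line
        try:
            rec = CensusRecord(cid, year, pairs, source)
        except ValidationError as exc:
            problems.append(f"line {line}: {exc}")
            continue
        grouped.setdefault(cid, []).append(rec)

    if problems:
        raise ValidationError(f"{path}:\n" + "\n".join(problems))

    out = []
    for cid, records in grouped.items():
        records.sort(key=lambda rec: rec.season_year)
        out.append(ColonySeries(colony_id=cid, records=tuple(records), name=cid))
    return out


def write_census(series: Iterable[ColonySeries], path: str | Path) -> None:
    """Write colony series to a census CSV.

    Counts are written with ``repr`` (shortest round-trip decimal), so
    ``read_census(write_census(x))`` reproduces every count bit-identically
    — fractional interpolated abundances included.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow([*CENSUS_COLUMNS, "source"])
        for ser in series:
            for rec in ser.records:
                writer.writerow(
                    [rec.colony_id, rec.season_year, repr(float(rec.breeding_pairs)), rec.source]
                )


# ---------------------------------------------------------------------------
# published trend-table fixture
# ---------------------------------------------------------------------------

_DM_PATTERN = re.compile(
    r"^\s*(\d+)\s*[°º]\s*(\d+(?:\.\d+)?)\s*[′'´]?\s*([NSEW])\s*$"
)


def parse_degree_minutes(text: str) -> float:
    """Parse a degree-minute coordinate like ``41°26'S`` to decimal degrees.

    Southern and western hemispheres are negative.  Used only for reporting,
    never for computation.
    """
    match = _DM_PATTERN.match(text)
    if match is None:
        raise ValidationError(f"cannot parse coordinate {text!r}")
    degrees, minutes, hemi = match.groups()
    value = float(degrees) + float(minutes) / 60.0
    if hemi in ("S", "W"):
        value = -value
    return value


def load_published_trends() -> list[PublishedTrendRow]:
    """Load the bundled 65-colony published trend table."""
    data = resources.files(__package__).joinpath("data", _FIXTURE_NAME)
    with resources.as_file(data) as fpath:
        df = pd.read_csv(fpath, dtype=str, keep_default_na=False, encoding="utf-8")
    rows = []
    for raw in df.itertuples(index=False):
        ci_low, ci_high = raw.ci_low.strip(), raw.ci_high.strip()
        ci = (float(ci_low), float(ci_high)) if ci_low and ci_high else None
        rows.append(
            PublishedTrendRow(
                row_number=int(raw.row_number),
                colony_id=raw.colony_id,
                name=raw.name,
                latitude=parse_degree_minutes(raw.lat_dm),
                longitude=parse_degree_minutes(raw.lon_dm),
                region=raw.region,
                printed_r=float(raw.printed_r),
                printed_lambda=float(raw.printed_lambda),
                printed_ci=ci,
                significant=bool(int(raw.significant)),
            )
        )
    if len(rows) != 65:
        raise ValidationError(f"trend-table fixture has {len(rows)} rows, expected 65")
    if len({row.row_number for row in rows}) != len(rows):
        raise ValidationError("trend-table fixture row numbers are not unique")
    return rows
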