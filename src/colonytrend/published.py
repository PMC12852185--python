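"""Published reference figures for the Argentine Magellanic penguin population.

These are the printed headline numbers of the reference national
assessment: the census pair behind the Malvinas/Falklands unit, national
abundance estimates for the reference years, and the trend tallies.  They
are *inputs* to the reproduction checks (the underlying per-colony census
series were never deposited) — nothing here is computed by this package.
"""

from __future__ import annotations

from .colony_data import CensusRecord, ColonySeries

#: The two archipelago-wide censuses of the Malvinas/Falklands unit:
#: ~1,300,000 breeding pairs in the 1989-1990 season, ~100,000 in 2019-2020
#: (seasons keyed to their first calendar year).
MALVINAS_CENSUS: tuple[tuple[int, float], ...] = ((1989, 1_300_000.0), (2019, 100_000.0))

#: Published interpolated abundance of the Malvinas unit in 1996.
MALVINAS_1996: float = 714_535.0

#: Published national totals excluding the Malvinas unit (breeding pairs).
NATIONAL_TOTALS_EXCL_MALVINAS: dict[int, float] = {
    1996: 863_670.0,
    2006: 909_713.0,
    2016: 990_393.0,
    2024: 1_280_900.0,
}

#: Published 2024 national total including the Malvinas unit.
NATIONAL_TOTAL_2024_WITH_MALVINAS: float = 1_348_100.0

#: Published totals for the >= 3-census-year stratum (excluding Malvinas).
THREE_PLUS_TOTALS: dict[int, float] = {1996: 599_320.0, 2024: 1_087_281.0}

#: Published totals for the two-census-year stratum (excluding Malvinas).
TWO_RECORD_TOTALS: dict[int, float] = {1996: 264_350.0, 2024: 193_620.0}

#: Published pooled finite growth rates.
AGGREGATE_LAMBDA: dict[str, float] = {
    "all_colonies": 0.993,
    "excluding_malvinas": 1.016,
    "three_plus_simple": 1.01932,
    "three_plus_empirical_bayes": 1.0192,
}

#: Published per-colony tallies: sign of the fitted trend over 65 colonies.
TREND_TALLY: dict[str, int] = {"increasing": 33, "declining": 32}


def malvinas_series() -> ColonySeries:
    """The Malvinas/Falklands archipelago as a single two-census colony unit."""
    records = tuple(
        CensusRecord("IM", year, pairs, source="archipelago-wide estimate")
        for year, pairs in MALVINAS_CENSUS
    )
    return ColonySeries(
        colony_id="IM",
        records=records,
        name="Islas Malvinas",
        latitude=-(51 + 47 / 60),
        longitude=-(59 + 31 / 60),
        region="Malvinas",
    )
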