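"""End-to-end pipeline: fit -> classify -> aggregate -> interpolate/project.

A :class:`RunConfig` captures every knob of a run; :func:`run_pipeline`
executes the stages, writes tidy CSVs, a plain-text summary report with the
trend tallies, and serialises the configuration verbatim into the output
directory, so any output file can be regenerated bit-identically from the
same configuration and inputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import aggregation
from .abundance_projection import (
    EXCLUDED_BACKWARD,
    AbundanceTable,
    ProjectionConfig,
    national_summary,
)
from .colony_data import ColonySeries, read_census
from .errors import ColonyTrendError
from .seeds import derive_seed
from .trend_estimation import (
    NEGATIVE_SIGNIFICANT,
    POSITIVE_SIGNIFICANT,
    STABLE,
    BootstrapSettings,
    TrendEstimate,
    fit_all,
)

log = logging.getLogger("colonytrend")

TREND_CSV_COLUMNS = [
    "colony_id",
    "method",
    "n_records",
    "r",
    "lambda",
    "var_r",
    "ci_low",
    "ci_high",
    "classification",
]


def _package_version() -> str:
    try:
        return metadata.version("colonytrend")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass(frozen=True)
class RunConfig:
    """Full provenance of a pipeline run."""

    census_path: str
    out_dir: str
    seed: int
    bootstrap_reps: int = 2000
    confidence_level: float = 0.95
    aggregate_boot_reps: int = 1000
    exclude: tuple[str, ...] = ("IM",)
    reference_years: tuple[int, ...] = (1996, 2006, 2016)
    projection_year: int = 2024
    recent_window: int = 3
    recent_colonies: tuple[str, ...] = ("EP", "ESL")
    malvinas_id: str = "IM"
    version: str = field(default_factory=_package_version)


def trends_to_frame(trends: Sequence[TrendEstimate]) -> pd.DataFrame:
    rows = []
    for t in trends:
        low, high = t.ci_lambda if t.ci_lambda is not None else (None, None)
        rows.append(
            {
                "colony_id": t.colony_id,
                "method": t.method,
                "n_records": t.n_records,
                "r": t.r,
                "lambda": t.lam,
                "var_r": t.var_r,
                "ci_low": low,
                "ci_high": high,
                "classification": t.classification,
            }
        )
    return pd.DataFrame(rows, columns=TREND_CSV_COLUMNS)


def frame_to_trends(df: pd.DataFrame) -> list[TrendEstimate]:
    """Rebuild trend estimates from a trends CSV (as written by this module)."""
    out = []
    for _, row in df.iterrows():
        ci = None
        if pd.notna(row["ci_low"]) and pd.notna(row["ci_high"]):
            ci = (float(row["ci_low"]), float(row["ci_high"]))
        out.append(
            TrendEstimate(
                colony_id=str(row["colony_id"]),
                method=str(row["method"]),
                r=float(row["r"]),
                lam=float(row["lambda"]),
                n_records=int(row["n_records"]),
                n_years_span=0,
                var_r=float(row["var_r"]) if pd.notna(row["var_r"]) else None,
                ci_lambda=ci,
                classification=str(row["classification"])
                if pd.notna(row["classification"])
                else None,
            )
        )
    return out


def tally_trends(trends: Sequence[TrendEstimate]) -> dict[str, int]:
    """Sign and significance tallies over a trend collection."""
    return {
        "n_colonies": len(trends),
        "increasing": sum(1 for t in trends if t.r > 0),
        "declining": sum(1 for t in trends if t.r < 0),
        "no_change": sum(1 for t in trends if t.r == 0),
        "positive_significant": sum(
            1 for t in trends if t.classification == POSITIVE_SIGNIFICANT
        ),
        "negative_significant": sum(
            1 for t in trends if t.classification == NEGATIVE_SIGNIFICANT
        ),
        "stable": sum(
            1
            for t in trends
            if t.classification == STABLE and t.ci_lambda is not None
        ),
    }


def _aggregate_rows(
    label: str,
    series: list[ColonySeries],
    trends: list[TrendEstimate],
    config: RunConfig,
) -> list[dict]:
    """Simple (all colonies) and EB (>= 3 records) aggregates for one subset."""
    rows = []
    if not trends:
        return rows
    weights = aggregation.simple_weights(series)
    simple = aggregation.aggregate_simple(
        trends,
        weights,
        n_boot=config.aggregate_boot_reps,
        seed=derive_seed(config.seed, "aggregate", label),
        confidence_level=config.confidence_level,
    )
    rows.append(
        {
            "subset": label,
            "method": simple.method,
            "n_colonies": simple.n_colonies,
            "r_general": simple.r_general,
            "lambda_general": simple.lambda_general,
            "ci_low": simple.ci_lambda[0] if simple.ci_lambda else None,
            "ci_high": simple.ci_lambda[1] if simple.ci_lambda else None,
        }
    )
    eb_trends = [t for t in trends if t.var_r is not None]
    eb_series = [s for s in series if s.colony_id in {t.colony_id for t in eb_trends}]
    if len(eb_trends) >= 2:
        comps = aggregation.eb_shrink(eb_trends, eb_series)
        eb = aggregation.aggregate_eb(comps)
        rows.append(
            {
                "subset": f"{label}_three_plus",
                "method": eb.method,
                "n_colonies": eb.n_colonies,
                "r_general": eb.r_general,
                "lambda_general": eb.lambda_general,
                "ci_low": eb.ci_lambda[0] if eb.ci_lambda else None,
                "ci_high": eb.ci_lambda[1] if eb.ci_lambda else None,
            }
        )
    return rows


def _totals_frame(tables: dict[int, AbundanceTable]) -> pd.DataFrame:
    rows = []
    for year, table in sorted(tables.items()):
        groups = table.group_totals()
        groups_excl = table.group_totals(exclude_malvinas=True)
        rows.append(
            {
                "year": year,
                "two_record": groups["two_record"],
                "three_plus_record": groups["three_plus_record"],
                "national": table.national_total(),
                "two_record_excl_malvinas": groups_excl["two_record"],
                "three_plus_record_excl_malvinas": groups_excl["three_plus_record"],
                "national_excl_malvinas": table.national_total(exclude_malvinas=True),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle to ``out_dir``.

    Returns a dict with the in-memory results (trends, aggregate rows,
    abundance tables, tallies) for programmatic use.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log.info("reading census data from %s", config.census_path)
    series = read_census(config.census_path)
    singles = [s.colony_id for s in series if s.n_records == 1]
    usable = [s for s in series if s.n_records >= 2]
    if singles:
        log.info("excluding %d single-record colonies: %s", len(singles), singles)

    settings = BootstrapSettings(
        seed=derive_seed(config.seed, "fit"),
        n_replicates=config.bootstrap_reps,
        confidence_level=config.confidence_level,
    )
    log.info("fitting trends for %d colonies", len(usable))
    trends = fit_all(usable, settings if config.bootstrap_reps > 0 else None)
    trends_df = trends_to_frame(trends)
    trends_df.to_csv(out_dir / "trends.csv", index=False)

    tallies = tally_trends(trends)

    agg_rows = _aggregate_rows("all", usable, trends, config)
    for excluded in config.exclude:
        kept_s = [s for s in usable if s.colony_id != excluded]
        kept_t = [t for t in trends if t.colony_id != excluded]
        if len(kept_t) != len(trends) and kept_t:
            agg_rows += _aggregate_rows(f"without_{excluded}", kept_s, kept_t, config)
    agg_df = pd.DataFrame(
        agg_rows,
        columns=[
            "subset",
            "method",
            "n_colonies",
            "r_general",
            "lambda_general",
            "ci_low",
            "ci_high",
        ],
    )
    agg_df.to_csv(out_dir / "aggregates.csv", index=False)

    proj_config = ProjectionConfig(
        reference_years=config.reference_years,
        projection_year=config.projection_year,
        recent_lambda_colonies=config.recent_colonies,
        recent_window=config.recent_window,
        malvinas_id=config.malvinas_id,
    )
    tables = (
        national_summary(usable, trends, proj_config) if trends else {}
    )
    abundance_rows = []
    for year, table in sorted(tables.items()):
        df = table.entries.copy()
        df.insert(1, "year", year)
        abundance_rows.append(df)
    abundance_df = (
        pd.concat(abundance_rows, ignore_index=True)
        if abundance_rows
        else pd.DataFrame(columns=["colony_id", "year", "abundance", "status", "stratum"])
    )
    abundance_df.to_csv(out_dir / "abundance.csv", index=False)
    totals_df = _totals_frame(tables)
    totals_df.to_csv(out_dir / "totals.csv", index=False)

    report = _format_report(config, singles, tallies, agg_df, totals_df)
    (out_dir / "report.txt").write_text(report, encoding="utf-8")
    with (out_dir / "run_config.yaml").open("w", encoding="utf-8") as handle:
        yaml.safe_dump(dataclasses.asdict(config), handle, sort_keys=True)
    log.info("report bundle written to %s", out_dir)

    return {
        "series": series,
        "trends": trends,
        "tallies": tallies,
        "aggregates": agg_df,
        "tables": tables,
        "totals": totals_df,
    }


def _format_report(
    config: RunConfig,
    singles: list[str],
    tallies: dict[str, int],
    agg_df: pd.DataFrame,
    totals_df: pd.DataFrame,
) -> str:
    lines = [
        "colonytrend pipeline report",
        "===========================",
        f"census file:        {config.census_path}",
        f"seed:               {config.seed}",
        f"bootstrap reps:     {config.bootstrap_reps}",
        f"confidence level:   {config.confidence_level}",
        "",
        f"single-record colonies excluded: {len(singles)}"
        + (f" ({', '.join(singles)})" if singles else ""),
        "",
        "trend tallies",
        "-------------",
    ]
    for key, value in tallies.items():
        lines.append(f"  {key:22s} {value}")
    lines += ["", "aggregate growth rates", "----------------------"]
    for row in agg_df.itertuples(index=False):
        ci = (
            f" [{row.ci_low:.4f} - {row.ci_high:.4f}]"
            if pd.notna(row.ci_low)
            else ""
        )
        lines.append(
            f"  {row.subset:24s} {row.method:16s} n={row.n_colonies:<4d} "
            f"lambda={row.lambda_general:.4f}{ci}"
        )
    lines += ["", "abundance totals (breeding pairs)", "---------------------------------"]
    for row in totals_df.itertuples(index=False):
        lines.append(
            f"  {int(row.year)}: national={row.national:,.0f} "
            f"(excl. {config.malvinas_id}: {row.national_excl_malvinas:,.0f})"
        )
    lines.append("")
    return "\n".join(lines)
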