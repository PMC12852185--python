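"""Pooling colony-level trends into an overall growth rate.

Two complementary aggregation schemes are implemented:

(a) *Simple weighting* — the pooled instantaneous rate is a weighted mean
    of colony rates, with weight

        w_i = Nbar_i * Y_i

    (mean observed abundance times number of census years), so large,
    well-monitored colonies dominate.  Applicable to every colony with at
    least two census years.

(b) *Empirical-Bayes shrinkage* — colony rates estimated with high
    sampling variance are pulled toward the cross-colony mean before
    pooling.  The among-colony variance is estimated by moments,

        tau2 = max(V_t - vbar_t, 0)

    where V_t is the sample variance of the colony rates and vbar_t the
    mean of their sampling variances.  Each colony's shrinkage weight is
    w_tb = v_t / (v_t + tau2); the shrunk rate is
    t_b = tbar * w_tb + t * (1 - w_tb) with variance v_tb = w_tb * tau2.
    Shrunk rates are pooled with abundance weights

        wA_i = (1 / T_i) * sum over census years of C_{i,t} / sum_j C_{j,t}

    (a colony's average share of the total counted population over its own
    census years; year totals run over colonies observed in that year),
    renormalised to sum to one.  This path requires a sampling variance and
    is therefore restricted to colonies fitted by log-linear regression.

In both schemes lambda_general = exp(r_general).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .colony_data import ColonySeries
from .errors import AlignmentError, DegenerateInputError, ValidationError
from .trend_estimation import TrendEstimate

SIMPLE = "simple"
EMPIRICAL_BAYES = "empirical_bayes"


@dataclass(frozen=True)
class ColonyWeight:
    """Simple-weighting components for one colony: w = Nbar * Y."""

    colony_id: str
    mean_abundance: float
    n_years: int
    weight: float


@dataclass(frozen=True)
class EBComponents:
    """Per-colony and global pieces of the empirical-Bayes computation.

    ``per_colony`` columns: colony_id, trend, var_t, bayes_weight,
    shrunk_trend, shrunk_var, abundance_weight.
    """

    per_colony: pd.DataFrame
    mean_trend: float
    among_var: float
    mean_within_var: float
    tau2: float


@dataclass(frozen=True)
class AggregateTrend:
    """A pooled growth rate with the components that produced it."""

    method: str
    r_general: float
    lambda_general: float
    n_colonies: int
    ci_lambda: Optional[tuple[float, float]] = None
    variance: Optional[float] = None
    components: object = None


def _align(
    trends: Sequence[TrendEstimate], other_ids: Iterable[str], other_name: str
) -> None:
    trend_ids = {t.colony_id for t in trends}
    other_ids = set(other_ids)
    if trend_ids != other_ids:
        missing = sorted(other_ids - trend_ids)
        extra = sorted(trend_ids - other_ids)
        raise AlignmentError(
            f"trend and {other_name} colony sets differ: "
            f"missing trends for {missing}, trends without {other_name} for {extra}"
        )


def simple_weights(series: Iterable[ColonySeries]) -> list[ColonyWeight]:
    """Compute w_i = Nbar_i * Y_i for each colony (>= 2 census years each)."""
    out = []
    for ser in series:
        if ser.n_records < 2:
            raise ValidationError(
                f"colony {ser.colony_id}: single-record colonies must be "
                "excluded before weighting"
            )
        mean_abundance = float(ser.counts.mean())
        out.append(
            ColonyWeight(
                colony_id=ser.colony_id,
                mean_abundance=mean_abundance,
                n_years=ser.n_records,
                weight=mean_abundance * ser.n_records,
            )
        )
    return out


def aggregate_simple(
    trends: Sequence[TrendEstimate],
    weights: Sequence[ColonyWeight],
    *,
    n_boot: int = 0,
    seed: Optional[int] = None,
    confidence_level: float = 0.95,
) -> AggregateTrend:
    """Weighted-mean pooled rate: r_general = sum(r_i w_i) / sum(w_i).

    With ``n_boot`` > 0 a nonparametric bootstrap over colonies (resampling
    colonies with replacement and recomputing the weighted mean) yields a
    percentile interval for lambda_general; ``seed`` is then required.
    """
    if not trends:
        raise DegenerateInputError("cannot aggregate an empty trend collection")
    _align(trends, (w.colony_id for w in weights), "weight")
    w_by_id = {w.colony_id: w.weight for w in weights}
    r = np.array([t.r for t in trends], dtype=float)
    w = np.array([w_by_id[t.colony_id] for t in trends], dtype=float)
    if w.sum() <= 0:
        raise DegenerateInputError("total weight is zero")
    r_general = float((r * w).sum() / w.sum())

    ci = None
    if n_boot > 0:
        if seed is None:
            raise ValueError("seed is required when bootstrapping the aggregate")
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, r.size, size=(n_boot, r.size))
        rb, wb = r[idx], w[idx]
        reps = (rb * wb).sum(axis=1) / wb.sum(axis=1)
        alpha = 1.0 - confidence_level
        low, high = np.quantile(np.exp(reps), [alpha / 2.0, 1.0 - alpha / 2.0])
        ci = (float(low), float(high))

    return AggregateTrend(
        method=SIMPLE,
        r_general=r_general,
        lambda_general=math.exp(r_general),
        n_colonies=len(trends),
        ci_lambda=ci,
        components=list(weights),
    )


def abundance_weights(series: Sequence[ColonySeries]) -> pd.Series:
    """Average population-share weights wA, renormalised to sum to one.

    For each census year of colony i, the colony's share is its count
    divided by the summed counts of all colonies observed in that year;
    wA_i is the mean share over the colony's own census years.  Years in
    which a colony was not surveyed contribute nothing to its average
    (unobserved counts are unknown, not zero).
    """
    year_totals: dict[int, float] = {}
    for ser in series:
        for rec in ser.records:
            year_totals[rec.season_year] = (
                year_totals.get(rec.season_year, 0.0) + rec.breeding_pairs
            )
    shares = {}
    for ser in series:
        share = [
            rec.breeding_pairs / year_totals[rec.season_year] for rec in ser.records
        ]
        shares[ser.colony_id] = float(np.mean(share))
    weights = pd.Series(shares, dtype=float)
    return weights / weights.sum()


def eb_shrink(
    trends: Sequence[TrendEstimate], series: Sequence[ColonySeries]
) -> EBComponents:
    """Moment-based empirical-Bayes shrinkage of colony trends.

    Every trend must carry a sampling variance (log-linear fits); at least
    two colonies are needed for the among-colony variance.  When the moment
    estimate of tau2 is negative it is truncated at zero, in which case
    every w_tb = 1 and all trends shrink fully to the mean.
    """
    if len(trends) < 2:
        raise DegenerateInputError(
            "empirical-Bayes shrinkage needs >= 2 colonies "
            "(among-colony variance undefined otherwise)"
        )
    for t in trends:
        if t.var_r is None:
            raise ValidationError(
                f"colony {t.colony_id}: no sampling variance "
                f"(method {t.method}); the empirical-Bayes path needs log-linear fits"
            )
    _align(trends, (s.colony_id for s in series), "series")

    t_arr = np.array([t.r for t in trends], dtype=float)
    v_arr = np.array([t.var_r for t in trends], dtype=float)
    mean_trend = float(t_arr.mean())
    among_var = float(t_arr.var(ddof=1))
    mean_within = float(v_arr.mean())
    tau2 = max(among_var - mean_within, 0.0)

    if tau2 == 0.0:
        w_tb = np.ones_like(v_arr)
    else:
        w_tb = v_arr / (v_arr + tau2)
    shrunk = mean_trend * w_tb + t_arr * (1.0 - w_tb)
    shrunk_var = w_tb * tau2

    w_a = abundance_weights(series)
    ids = [t.colony_id for t in trends]
    per_colony = pd.DataFrame(
        {
            "colony_id": ids,
            "trend": t_arr,
            "var_t": v_arr,
            "bayes_weight": w_tb,
            "shrunk_trend": shrunk,
            "shrunk_var": shrunk_var,
            "abundance_weight": w_a.loc[ids].to_numpy(),
        }
    )
    return EBComponents(
        per_colony=per_colony,
        mean_trend=mean_trend,
        among_var=among_var,
        mean_within_var=mean_within,
        tau2=tau2,
    )


def aggregate_eb(
    components: EBComponents, *, squared_weight_variance: bool = False
) -> AggregateTrend:
    """Pool shrunk trends with abundance weights.

    r_general = sum(wA * t_b).  The pooled variance is the matching
    weighted mean of the shrunk variances, sum(wA * v_tb); set
    ``squared_weight_variance`` for the variance-of-a-weighted-mean form
    sum(wA**2 * v_tb) instead.  The interval is the normal interval on r,
    exponentiated.
    """
    df = components.per_colony
    w = df["abundance_weight"].to_numpy()
    if abs(w.sum() - 1.0) > 1e-9:
        raise AlignmentError("abundance weights do not sum to 1 after renormalisation")
    r_general = float((w * df["shrunk_trend"]).sum())
    if squared_weight_variance:
        variance = float((w**2 * df["shrunk_var"]).sum())
    else:
        variance = float((w * df["shrunk_var"]).sum())
    half = 1.959963984540054 * math.sqrt(variance)
    ci = (math.exp(r_general - half), math.exp(r_general + half))
    return AggregateTrend(
        method=EMPIRICAL_BAYES,
        r_general=r_general,
        lambda_general=math.exp(r_general),
        n_colonies=len(df),
        ci_lambda=ci,
        variance=variance,
        components=components,
    )
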