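# Methods

`colonytrend` implements a national-scale trend and abundance assessment
for colonially breeding seabirds censused in breeding pairs, of the kind
used for the Magellanic penguin (*Spheniscus magellanicus*) along the
Argentine coast. This note records the models, the parameter choices that
matter, and the design decisions taken where the methodology was open.

## Growth model and per-colony estimators

Each colony is modelled by discrete-time, density-independent exponential
growth with multiplicative observation error:

    N_t = N_0 · λ^(t − t_0),    r = ln λ,    observed N_t = true N_t · ε_t

with ln ε_t ~ Normal(0, σ²). There is no process (demographic) noise and
no density dependence in the model. Breeding seasons straddle two calendar
years; a season is keyed to its first calendar year everywhere (the
1989–1990 season is year 1989). Counts are stored as reals: observed
censuses are typically integers, but interpolated and projected abundances
are fractional and are only rounded at report time.

Estimators, by data availability:

* **≥ 3 census years** — ordinary least squares of ln N_t on t;
  r is the slope, λ = e^r, and `var_r` is the squared standard error of
  the slope. Multiplicative error becomes additive on the log scale,
  which is the standard reading of the model.
* **Exactly 2 census years** — the direct two-point rate
  λ = (N_t/N_0)^(1/(t−t_0)); algebraically identical to the OLS slope
  through the two log-counts, but with no variance and no interval.
* **1 census year** — no trend information; the colony is excluded from
  trend, aggregation and projection analyses (but reported as excluded).

Zero counts are errors, not data: the log model is undefined at N = 0 and
the package refuses to guess an offset. Callers must pre-filter or apply
an explicit offset themselves.

## Bootstrap confidence intervals

Intervals for the log-linear fit come from a residual bootstrap: the
regression residuals are resampled with replacement, added back to the
fitted log-values, and the slope re-estimated per replicate (2,000
replicates by default; the seed is a mandatory argument, with per-colony
seeds derived from one base seed so results are independent of iteration
order).

Two small-sample calibration choices matter, because colony series are
short (3–6 censuses are typical):

1. **Leverage rescaling.** Raw OLS residuals have variance σ²(1 − h_ii);
   resampling them underestimates the error variance by a factor of about
   (n − 2)/n, which is severe at n = 5 or 6. Residuals are therefore
   divided by √(1 − h_ii) and re-centred before resampling.
2. **Expanded percentile interval.** The plain percentile interval has an
   implicit normal-quantile multiplier where a Student t with n − 2
   degrees of freedom is warranted. By default the quantile levels are
   widened so the implied multiplier is t_{n−2} rather than z
   (Hesterberg's expanded percentile interval). Measured coverage of the
   nominal 95% interval on simulated 6-census series with log-scale noise
   sd 0.1 is ≈ 0.93 (≈ 0.91 at 5 censuses); the plain percentile interval
   measures ≈ 0.86 and is available via `interval_method="percentile"`.

At n ≤ 4 the adjusted tail levels fall below the resolution of the
discrete resample space and the interval saturates at the extremes of the
replicate distribution — honest, very conservative intervals for
extremely short series.

A perfect exponential series has zero residuals and a zero-width interval.
Identical seeds give bit-identical intervals.

## Trend classification

λ > 1 is an increase and λ < 1 a decline. "λ = 1" is measure-zero, so
stability is operationalised through the interval: with a CI, a colony is
`positive_significant` (CI entirely above 1), `negative_significant`
(entirely below 1) or `stable` (CI contains 1). Without a CI (two-point
colonies) only the sign of r is available and the label is flagged
`_unsupported`. Significance is CI-based, not a t-test on the slope,
matching the CI-centric reporting the pipeline produces.

## Aggregation

**Simple weighting** pools all colonies with ≥ 2 censuses:
w_i = N̄_i · Y_i (mean observed abundance × number of census years),
r_general = Σ r_i w_i / Σ w_i, λ_general = e^(r_general). No interval
recipe is prescribed by the methodology this follows; the package offers a
seeded nonparametric bootstrap over colonies (resample colonies with
replacement, recompute the weighted mean; 1,000 replicates, percentile
interval).

**Empirical-Bayes shrinkage** applies only to colonies with a sampling
variance (≥ 3 censuses). With t the colony rates and v_t their variances:

* among-colony variance V_t: sample variance of the rates (n − 1
  denominator — the source does not specify; the sample form is standard);
* τ² = max(V_t − v̄_t, 0). The moment estimate can go negative; truncation
  at zero is standard practice and keeps the shrinkage weight in [0, 1].
  At τ² = 0 every w_tb = 1 and all rates shrink fully to the mean.
* w_tb = v_t / (v_t + τ²); t_b = t̄ w_tb + t (1 − w_tb); v_tb = w_tb τ².
  A perfectly measured rate (v_t = 0) is not shrunk. t̄ is the unweighted
  mean of the colony rates.
* abundance weights wA_i = (1/T_i) Σ_{t∈T_i} C_{i,t} / Σ_j C_{j,t}: a
  colony's average share of the total counted population over its own
  census years. Year totals include only colonies observed in that year —
  unobserved counts are unknown, not zero. Weights are renormalised to
  sum to exactly 1.
* pooled rate t_{b−A} = Σ wA t_b, with variance Σ wA v_tb (the weighted
  mean of shrunk variances, mirroring the rate formula; the
  variance-of-a-weighted-mean form Σ (wA)² v_tb is available via
  `squared_weight_variance=True`). The interval is the normal interval on
  r, exponentiated.

Both pooled rates are convex combinations of the colony rates and agree
exactly when all colonies share one rate.

## Interpolation and projection

Abundance at a target year (defaults 1996, 2006, 2016; projection to
2024) is evaluated on the colony's trajectory anchored at the latest
census at or before the target year. Anchoring near the target limits
compounded error relative to always anchoring at N_0 (for two-point
colonies the two conventions share λ, and for the Malvinas unit this rule
reproduces the published 1996 figure from the 1989 anchor). Target years
equal to census years return the observed count exactly. Years before a
colony's first census are **excluded** — flagged `excluded_backward` and
counted as zero, never silently dropped — unless backward extrapolation
is explicitly enabled (testing only).

Colonies that exploded during establishment (El Pedral, Estancia San
Lorenzo) are refit on their most recent records only (window default 3;
two-point if the window is 2) and that recent-phase λ is used for target
years from 2016 onward. The window and colony list are configuration,
recorded in the run provenance, not hard-coded behaviour.

National tables stratify colonies by record count (exactly 2 vs ≥ 3),
determined from the data, and report totals with and without the
Malvinas/Falklands unit. Percent changes are 100·(after − before)/before,
rounded to integer percent at report time only.

## Field census estimator

The circular-plot design uses 5.65 m-radius plots (π r² ≈ 100.3 m², the
nominal "100 m²") every 50 m along transects 100 m apart; an active nest
holds an adult or a pair with eggs. Colony abundance is estimated by
mean-density expansion: mean nests per plot ÷ plot area × colony area.
This design-based estimator is unbiased on a homogeneous Poisson nest
field (verified by simulation). Spatial density interpolation (natural
neighbour surfaces over plot coordinates and GIS colony polygons) is out
of scope; the geometric plot area is the default, the nominal 100 m² a
flag. Outputs name the estimator used.

## Synthetic data

The generator draws colonies from the generating process the estimators
assume, with structure matching the reference monitoring compilation:

| parameter | default | rationale |
|---|---|---|
| colonies | 73 | compiled national colony count |
| survey strata | 8 / 33 / 32 single / two / ≥3-record | the published data-availability stratification |
| true r | Normal(0.01, 0.06) | spans the published per-colony range (−0.32 to 0.56) in its tails |
| N_0 | log-uniform 10²–10⁶ | published colony sizes span this range |
| observation noise | lognormal, sd 0.1 on the log scale | a plausible census CV of ~10% |
| census years | integers in 1985–2024 | the study window |
| ≥3-record colonies | 3–10 censuses | typical monitoring coverage |
| dominant decliner | id "IM", 1.3 × 10⁶ pairs in 1989, r = −0.0855, two records | the Malvinas/Falklands unit |

The generator emulates sampling error and uneven coverage but *not*
demographic stochasticity, density dependence, catastrophes, observer
bias, or dispersal between colonies. Passing recovery tests therefore
show that the estimators are correct under the model's own assumptions —
not that real census series satisfy those assumptions.

## Validation problem sizes

The test suite measures bootstrap coverage on 1,000 simulated 6-census
series (and 500 five-census series), recovery bias on 10,000 colonies
(alternating noiseless and sd 0.1), and Poisson-field unbiasedness on 200
plots — sizes at which Monte-Carlo error is small relative to the bands
checked while the whole suite runs in seconds.

## Known limitations

* No autocorrelated-error or state-space trend models; censuses are
  treated as independent given the trend.
* Two-point rates carry no uncertainty and enter the simple aggregate
  only; the EB path requires ≥ 3 censuses.
* Projected totals are point values; no uncertainty is propagated into
  interpolated or projected abundances.
* The bundled 65-colony reference table stores printed values as printed;
  one row (El Pedral) is internally inconsistent in its source (its λ is
  not the rounding of e^r), and the package reports, rather than repairs,
  that inconsistency.
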