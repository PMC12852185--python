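# colonytrend

Growth-rate estimation, trend aggregation and abundance projection for
colony census time series — built for national-scale assessments of the
Magellanic penguin (*Spheniscus magellanicus*) along the Argentine coast,
and usable for any colonially breeding species censused in breeding pairs.

Wildlife monitoring data of this kind are sparse and uneven: a few
flagship colonies have decades of annual censuses, most have two or three
scattered counts, and some have a single record. `colonytrend` turns such
data into colony trends and national abundance trajectories:

* **Per-colony trends.** Each colony follows a discrete-time,
  density-independent exponential model N_t = N₀·λ^(t−t₀) with
  multiplicative error, where λ is the finite growth rate and r = ln λ.
  Colonies with ≥ 3 censuses are fitted by log-linear regression with
  residual-bootstrap confidence intervals; colonies with exactly 2 get the
  direct two-point rate λ = (N_t/N₀)^(1/(t−t₀)); single-record colonies
  are excluded. Trends are classified increasing / declining / stable by
  whether the interval excludes λ = 1.
* **Pooled national trend.** Two schemes: a simple weighted mean with
  w_i = N̄_i·Y_i (mean abundance × census years), and empirical-Bayes
  shrinkage, which pulls noisy colony rates toward the cross-colony mean
  in proportion to v_t/(v_t + τ²) with τ² = max(V_t − v̄_t, 0), then pools
  the shrunk rates with abundance-share weights.
* **Abundance interpolation and projection.** Colony trajectories are
  evaluated at reference years (1996, 2006, 2016) and projected to 2024,
  anchored at observed censuses, never extrapolated backward before a
  colony's first record; totals are stratified by survey coverage and
  reported with and without the Malvinas/Falklands unit.
* **Plot-census estimation** (circular 100 m² plots, mean-density
  expansion) and a **synthetic-data generator** with known ground truth
  for validating the whole pipeline.

The package bundles a machine-readable transcription of the published
65-colony trend table (IDs, coordinates, provinces, printed r, λ, CIs,
significance flags) as its reference object. See `docs/methods.md` for
the full methodology.

## Worked example

The Malvinas/Falklands archipelago is treated as a single colony unit
with two archipelago-wide censuses: ~1,300,000 breeding pairs in the
1989–1990 season and ~100,000 in 2019–2020.

```python
from colonytrend import fit_two_point, interpolate_to_year, project_to_year
from colonytrend.published import malvinas_series

series = malvinas_series()
est = fit_two_point(series)
print(f"lambda={est.lam:.4f}  r={est.r:.4f}")

n96, status = interpolate_to_year(series, est, 1996)
n24 = project_to_year(series, est, 2024)
print(f"1996: {n96:,.0f} pairs ({status})")
print(f"2024: {n24:,.0f} pairs ({100*(1-n24/n96):.1f}% decline since 1996)")
```

```
lambda=0.9181  r=-0.0855
1996: 714,535 pairs (interpolated)
2024: 65,214 pairs (90.9% decline since 1996)
```

The colony lost about 8.2% of its breeding pairs per year (λ = 0.918):
interpolating 7 years forward from the 1989 census gives the 1996
abundance, and projecting 5 years beyond the 2019 census gives the 2024
abundance — a > 90% decline over three decades.

The same flow from the shell, on simulated data:

```sh
colonytrend simulate --seed 7 --out-census census.csv --out-truth truth.csv
colonytrend fit census.csv --out trends.csv --seed 7
colonytrend aggregate census.csv trends.csv --method eb --out-summary agg.csv
colonytrend report census.csv --out-dir run --seed 7
```

`report` writes `trends.csv`, `aggregates.csv`, `abundance.csv`,
`totals.csv`, a plain-text summary with trend tallies, and
`run_config.yaml` capturing every setting — the same configuration and
seed regenerate every numeric output byte-identically.

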