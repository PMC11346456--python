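# abxdyn

Discovery-and-resistance dynamics of antibacterial drug classes.

Every antibacterial drug class has a finite clinical lifetime: some years
after its discovery, resistance to it is first detected. Meanwhile new
classes are discovered from what is, in effect, a finite natural-product
pool — early screening yields novelty quickly (the golden age), later
screening mostly rediscovers known chemistry. `abxdyn` packages the
quantitative core of that story for epidemiologists and discovery
strategists working from class-timeline tables (one row per class:
discovery year, first clinical use year, first resistance year):

* **Time to resistance** is modelled as an exponential waiting time with
  constant hazard λ per year, so the clinical *half-life* of a class is
  the median t½ = ln 2 / λ. Classes with no resistance detected by the
  observation year are right-censored and contribute exposure but no
  event. The censored MLE is the classic λ̂ = events / total exposure; a
  binned Poisson maximum-likelihood variant fits the histogram of
  observed intervals directly, and a seeded percentile bootstrap gives a
  confidence interval for t½.
* **Class discovery** is a coupon-collector process: screening draws
  arrive as a Poisson process at rate *n* per year, starting after a lag
  t_lag from an origin year t₀, each draw landing uniformly on one of *k*
  classes. The expected discovered count is
  E[D(t)] = k (1 − e^(−n τ / k)), τ = max(0, t − t₀ − t_lag),
  and (k, n, t_lag) are fitted by Poisson maximum likelihood on yearly
  new-class counts.
* **The repertoire race**: with per-class resistance clocks starting at
  discovery, the expected number of classes with detected resistance is
  R(t) = ∫ D′(s) (1 − e^(−λ(t−s))) ds, and the clinically precious
  quantity is U(t) = D(t) − R(t), the classes with resistance *not yet*
  detected — a curve that rises through the golden age and falls once
  resistance accrual outpaces discovery.

A seeded generative simulator produces synthetic timeline tables with
exactly this structure, so every fitting stage is testable end to end
without external data.

## Worked example

```python
import numpy as np
from abxdyn import (DiscoveryParams, SimulationConfig, YearlyCounts,
                    compute_intervals, fit_discovery, fit_exponential_mle,
                    fit_resistance_detection, half_life_ci, simulate_timelines,
                    undetected_curve)

truth = DiscoveryParams(k=30, n=1.5, t_lag=28, t0=1900)
cfg = SimulationConfig(dparams=truth, half_life=15.0, horizon_year=2020, seed=42)
table = simulate_timelines(cfg)
print(f"simulated classes: {len(table)}")

iv = compute_intervals(table, observation_year=2020)
fit = fit_exponential_mle(iv, include_censored=True)
lo, hi = half_life_ci(iv, level=0.95, n_boot=1000, seed=1)
print(f"half-life: {fit.half_life:.1f} y (95% CI {lo:.1f}-{hi:.1f}), "
      f"{fit.n_events} events, {fit.n_censored} censored")

counts = YearlyCounts.from_years(table.discovery_years, start_year=1900, end_year=2020)
dfit = fit_discovery(counts, k_max=200, t_lag_max=60, t0=1900)
print(f"discovery: k={dfit.params.k}, n={dfit.params.n:.2f}/y, t_lag={dfit.params.t_lag:.0f} y")

rcounts = YearlyCounts.from_years(table.resistance_years, start_year=1900, end_year=2020)
det = fit_resistance_detection(rcounts, dfit)
print(f"detection-side half-life: {det.half_life:.1f} y")

curve = undetected_curve(dfit.params, det.half_life, np.arange(1900, 2021))
peak = curve.expected_undetected.argmax()
print(f"peak not-yet-resistant repertoire: {curve.expected_undetected[peak]:.1f} "
      f"classes in {int(curve.years[peak])}")
```

Output:

```
simulated classes: 30
half-life: 13.6 y (95% CI 8.2-21.2), 28 events, 2 censored
discovery: k=30, n=1.70/y, t_lag=28 y
detection-side half-life: 11.1 y
peak not-yet-resistant repertoire: 10.5 classes in 1945
```

The simulator drew 30 classes from a 30-class pool over 120 years; the
censoring-aware exponential fit estimates the resistance half-life at
13.6 years (truth 15, well inside the bootstrap CI), the discovery fit
recovers the pool size, sampling rate and the 28-year lag exactly, and
the stagewise detection-side fit recovers the half-life again from
yearly first-resistance counts alone. With ~30 classes the estimates
scatter at the ±20–30% level from seed to seed — that sampling spread is
a property of the data size, not the estimator.

Estimators follow scikit-learn conventions (`ExponentialSurvival`,
`CouponCollectorDiscovery`, `ResistanceDetection`: `fit`, `predict`,
`get_params`, fitted attributes with trailing underscores); the
module-level functions above are thin wrappers over them.

## Command line

```sh
abxdyn simulate --k 30 --n 1.5 --tlag 28 --t0 1900 --half-life 15 \
       --horizon 2020 --seed 1 --out sim.csv
abxdyn validate sim.csv
abxdyn fit-resistance sim.csv --include-censored --seed 1
abxdyn fit-discovery sim.csv --t0 1900
abxdyn curves sim.csv --fit --out curves.csv
abxdyn report --input sim.csv --seed 1 --report-out report.json --plot fig.png
```

`report` runs the full pipeline (intervals → half-life + CI → discovery
fit → dynamics curves) and writes a versioned JSON report whose
provenance block (input or simulation config, seeds, version) suffices
to reproduce every number in it. A YAML config file can replace the
flags (`--config`), with flags taking precedence.

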