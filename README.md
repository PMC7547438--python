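# hipwait

Surgical demand and time to hip fracture surgery: an analysis pipeline for
abstract-level hospital discharge data.

Most hip fracture patients need surgery within a two-day benchmark, but the
queue they join varies day to day. `hipwait` measures that demand per
admission as a **clearance time** — the days needed to operate on every
preoperative hip-fracture patient already in the hospital if it worked at its
maximum weekly rate with no new arrivals —

    C = Q / (S / 7),

with `Q` the preoperative census on the admission day and `S` the hospital's
maximum weekly number of hip fracture surgeries in the fiscal quarter, and
classifies admissions as *benchmark* (C ≤ 2), *medium* (≤ 4), *high* (≤ 6) or
*excessive* (7+ days) demand. It then estimates how demand shifts the time to
surgery with an interval-censored log-normal accelerated failure time model

    log T = x'β + b0 + b1·d + σ ε,

where surgery on inpatient day N is observed as T ∈ (N−1, N] (right-censored
at 7 days), `b0`/`b1` are hospital random intercepts and random demand
slopes integrated out by adaptive Gauss–Hermite quadrature, and standard
errors are hospital-clustered sandwich estimates. A coefficient β is
reported as the percent change in the median time to surgery,
(e^β − 1)·100%. Turnbull's NPMLE provides the nonparametric cumulative
probability of surgery by day, per demand group.

Because real discharge databases are confidential, the package includes a
first-class synthetic-data generator: hospitals with quarter-varying
capacity, Poisson admissions, FIFO capacity-limited scheduling that produces
realistic preoperative queues, transfer episodes split across contiguous
abstracts, and configurable true demand effects — so the whole pipeline,
from abstract merging to effect recovery, is testable end to end.

Audience: health-services researchers and biostatisticians working with
administrative discharge data (or teaching/validating interval-censored AFT
methods on realistic synthetic cohorts).

## Worked example

```python
import numpy as np
import hipwait as hw

# 1. synthetic discharge abstracts (12 hospitals, 2 years, known effects)
cfg = hw.SimulationConfig(n_hospitals=12, start="2004-01-01",
                          end="2005-12-31", seed=7)
abstracts, truth, _ = hw.simulate_cohort(cfg)

# 2. care episodes and cohort exclusions
episodes = hw.merge_episodes(abstracts)
cohort, excluded = hw.apply_exclusions(episodes)

# 3. clearance-time demand per admission
cohort = cohort.join(hw.assess_demand(cohort))
cohort = cohort[cohort.demand_category.notna()]
print("cohort:", len(cohort), "episodes;", excluded)
print(cohort.demand_category.value_counts(normalize=True).round(3).to_string())

# 4. nonparametric probability of surgery within 2 days, benchmark demand
bench = cohort[cohort.demand_category == "benchmark"]
curve = hw.npmle_from_days(bench.surgery_inpatient_day)
print(f"benchmark demand: {100*hw.cdf_at(curve, 2):.0f}% operated within 2 days")

# 5. effect recovery: sample from the AFT model and refit
df = hw.simulate_aft_dataset(n_hospitals=100, episodes_per_hospital=100,
                             tau_intercept=0.1, rng=np.random.default_rng(7))
fit = hw.fit_aft(df, covariates=None, random_effects="intercept")
for cat in ("medium", "high", "excessive"):
    e = hw.percent_change(fit, f"demand[{cat}]")
    print(f"{cat:10s} {e.pct_change:+5.1f}%  (95% CI {e.ci_low:.1f} to {e.ci_high:.1f})")
```

Output:

```
cohort: 4486 episodes; {'no_surgery': 8, 'low_volume_hospital': 0}
demand_category
medium       0.473
benchmark    0.383
high         0.134
excessive    0.010
benchmark demand: 64% operated within 2 days
medium      +5.1%  (95% CI 2.6 to 7.7)
high       +12.5%  (95% CI 8.2 to 16.9)
excessive  +27.9%  (95% CI 17.7 to 39.0)
```

Steps 1–4 exercise the data pipeline: merging transfer abstracts back into
episodes, excluding low-volume hospital-years, classifying each admission's
demand (here 38% benchmark, 1% excessive) and estimating the benchmark
group's day-2 surgery probability. Step 5 is the estimation check: the
model-based sampler embedded true effects of +5.1%, +12.2% and +22.0% on
the median time to surgery, and the interval-censored fit recovers them
within sampling error. Fitting the AFT model to the queue-simulated cohort
itself gives much larger demand effects, because a high census is a real
backlog that FIFO scheduling must work through — see
[docs/methods.md](docs/methods.md) for why that is a property of the
simulated mechanism, not an estimation artifact. `hw.predicted_median`
turns any fit into median days per group.

The same pipeline runs from the shell:

```bash
hipwait all --config docs/example_run.yaml --seed 7   # simulate → tables + curves
hipwait build --abstracts my_abstracts.csv --out run/ # or from your own CSV
```

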