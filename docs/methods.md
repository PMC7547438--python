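# Methods

`hipwait` estimates how surgical demand relates to time to hip fracture
surgery in abstract-level hospital discharge data. This note documents the
model, the demand metric, the synthetic-data generator, and the numerical and
design choices, in enough detail to reproduce or audit any stage.

## The analysis

### Unit of analysis: care episodes

Hospital discharge abstracts record single stays; a surgical transfer
produces two abstracts for one clinical trajectory. Abstracts with the same
patient identifier whose next admission falls on, or within one day of, the
running latest discharge are combined into one care episode (transitively).
Episode covariates are taken from the abstract containing the surgery (the
first abstract when none does), and the preoperative-transfer flag is set
when the surgery abstract is not the chronologically first. The one-day gap
is our operationalisation of "contiguous dates": same-day and next-day
transfers both link, anything longer is a new episode.

The analysis cohort drops episodes without a surgery date and episodes whose
surgery hospital performed 24 or fewer hip fracture surgeries in that
calendar year (low-volume exclusion; "annual" is read as calendar year, the
simplest auditable choice).

### Demand: clearance time

Demand at admission is measured by the *clearance time*

    C = Q / (S / 7)  days,

where `Q` is the number of preoperative hip-fracture patients present in the
admitting hospital on the day of admission (a patient is present
preoperatively on day *d* when admitted on or before *d* and not operated
before *d*), and `S` is the *maximum weekly service rate*: the largest
number of hip fracture surgeries the hospital performed in any single week
of the fiscal quarter containing the admission. Weeks are consecutive 7-day
blocks anchored at the quarter's first day; the final partial block still
counts (it can only lower the maximum, never inflate it). Fiscal quarters
follow the Canadian fiscal year (Q1 = April–June). Demand categories:

| category  | clearance time |
|-----------|----------------|
| benchmark | C ≤ 2 days     |
| medium    | 2 < C ≤ 4      |
| high      | 4 < C ≤ 6      |
| excessive | C > 6 ("7 or more days") |

Boundaries are closed on the right (`C = 2.0` is benchmark), matching the
"within 2 days / within 4 days" reading; because `Q` is an integer and the
rate `S/7` is constant within a quarter, `C > 6` coincides exactly with "at
least 7 days needed to drain the queue" (verified against a brute-force
queue-drain oracle in the acceptance suite).

Two conventions are genuinely ambiguous and are exposed as options, with
defaults documented here: the index patient **is** counted in `Q` (they are
part of the demand present on their admission day; `include_index=False` is
available), and raw `C` rather than `ceil(C)` is categorised (equivalent for
the category boundaries, see above). Episodes admitted in a hospital-quarter
with no surgeries have an undefined rate; they are flagged, counted, and
excluded from the demand analysis.

### Outcome and censoring

Time to surgery `T` is known only to inpatient-day resolution: surgery on
inpatient day `N` (admission day = day 1) places `T` in the interval
`(N−1, N]` days. Day-1 surgeries are left-censored (the log lower bound is
−∞), and surgeries after 7 inpatient days are right-censored at 7 — delays
beyond a week are attributed to medical instability rather than demand.

### Model

A log-normal accelerated failure time model with hospital random effects:

    log T_ij = x_ij' β + b0_i + b1_i · d_ij + σ ε_ij,   ε ~ N(0,1),

for episode *j* in hospital *i*, where `x` holds the intercept, indicators
for medium/high/excessive demand (benchmark = reference) and the adjustment
covariates (age group, sex, prefracture status, admission timing, admission
status, preoperative transfer, preoperative procedures, medical reason for
delay, hospital type, fracture type, procedure type, era, province), and
`d` is the ordinal demand score 0–3. `b0` is a random intercept and `b1` a
random demand slope, independent `N(0, τ0²)`, `N(0, τ1²)`.

*Random-effects design.* "Random coefficients for demand" is parameterised
by default as a single random slope on the ordinal score, alongside the
fixed category indicators. This keeps the integral two-dimensional (a full
category-wise slope would need four) while still letting the effect of
demand vary by hospital. The intercept–slope correlation is fixed at zero;
the model is exposed as `random_effects ∈ {none, intercept,
intercept_slope}`.

Each hospital's marginal likelihood integrates the product of interval
probabilities `Φ((log U − η)/σ) − Φ((log L − η)/σ)` over the random effects.
The integral is evaluated by adaptive Gauss–Hermite quadrature: a vectorised
Newton search finds each hospital's posterior mode and curvature (the
integrand is log-concave), and a 9-node (default; tensor-product in 2-D)
Hermite rule is centred and scaled there. A non-adaptive rule is available
(`adaptive=False`). On toy problems the 9-node adaptive rule agrees with
direct numerical integration to ~1e-9 and with a 15-node rule to <1e-6.

*Estimation.* BFGS on the unconstrained parameters `(β, log σ, log τ)` with
central-difference gradients; convergence at gradient sup-norm below `gtol`
(default 1e-5, accepted relative to sample size). Exactly observed log-times
(used by tests and calibration) enter through the normal density, so with no
censoring and no random effects the MLE reduces to least squares on logs.

*Uncertainty.* Model-based covariance is the inverse observed information
(numerical Hessian). The reported standard errors use the hospital-clustered
sandwich `A⁻¹ B A⁻¹` with `B = Σ_i s_i s_i'` built from per-hospital score
vectors and the small-sample factor `G/(G−1)`.

### Reported effects

A coefficient `β_k` multiplies the median time to surgery by `exp(β_k)`; we
report the percent change in the median, `(exp(β_k) − 1)·100`, with a Wald
95% CI transformed from the coefficient scale (`z = 1.96`). Group medians
come from a demand-only model as `exp(β0 + β_k)` with delta-method CIs;
adjusted medians, when requested, are evaluated at the cohort's modal
covariate profile (the profile behind published adjusted medians is not
identifiable from a printed table, so the modal profile is our documented
choice). The identity "percent change = median ratio − 1" holds exactly by
construction and is asserted in tests.

Subgroup analyses split the cohort by presence of a medical reason for delay
(a preoperative specialist-care-unit admission or a NICE-guideline-124
condition) and drop that covariate from the adjustment set.

### Nonparametric curves

Cumulative probabilities of surgery within *t* days since admission are
estimated per demand group by the Turnbull NPMLE: probability mass lives on
the innermost ("Turnbull") intervals of the censoring intervals, found by a
left/right endpoint scan, and masses are estimated by self-consistency EM
iterated until the largest mass change is below 1e-8. The EM log-likelihood
is monotone (asserted in tests). On the day grid the intervals are disjoint,
so any interval-censored NPMLE coincides with the counting estimate — the
choice of algorithm is inconsequential there, which is why EM (simple,
monotone) was chosen over convex-minorant methods. The CDF is evaluated
right-continuously at integer days; inside a support interval the NPMLE CDF
is not unique and evaluation raises with the interval bounds. Exact event
times are handled as degenerate intervals; on exact/right-censored data the
estimator reproduces Kaplan–Meier to 1e-8 (cross-checked against an
independent implementation).

## The synthetic cohort generator

The generator produces discharge abstracts with the statistical structure
the analysis assumes, with known true effects, so every stage is testable
without access to confidential discharge data.

Per hospital: homogeneous Poisson admissions (default 0.52/day ≈ 190/year,
the published average annual hospital volume); a capacity calendar giving
`round(base × multiplier_q)` surgical slots per week (default base 7/week,
quarter multipliers (1.0, 0.9, 1.0, 1.1) for mild seasonal variation),
spread over the days of quarter-anchored weeks — the same weeks over which
the analysis measures the maximum weekly rate. Patient covariates are
sampled from the published cohort's marginal frequencies; hospital type and
province are hospital-level draws; era derives from the admission year.
Medical reasons for delay (SCU admission and/or NICE-124 condition) have
6.7% prevalence.

Time to surgery is generated from the same AFT model the package fits:

    log T = log 1.5 + effect[category] + 0.39·delay + b0 + b1·score + 0.6·ε

with default true demand effects log(1.051), log(1.122), log(1.220) —
+5.1%/+12.2%/+22.0% on the median — hospital SDs τ0 = 0.10, τ1 = 0.03, and
a 0.39 log-shift for medical-delay patients (reproducing the ≈0.7-day longer
medians of that subgroup). The baseline 1.5-day median and σ = 0.6 are
calibrated to the published benchmark-demand day curve: the distribution
implies 68%, 95% and 99% of baseline draws within 2, 4 and 7 days, matching
the reported 68/94/98% (in queue-simulated cohorts residual congestion
lowers the realized benchmark-group day-2 share by a few points; the
acceptance script reports the realized values). The draw is discretised to inpatient day `N = ceil(T)`
and then scheduled: patients become ready on their drawn day and are
operated first-in-first-out within hospital, never exceeding the day's
slots. With capacity slack the schedule equals the draw (asserted in tests);
under congestion queueing adds delay on top of the modelled effects.

The demand category that receives the injected effect is computed *online*
during simulation from the simulator's own queue census and the quarter's
nominal weekly capacity, so the generative effect conditions on the same
kind of covariate the model fits. Two things still separate a regression on
queue-generated data from the injected effects, both deliberate properties
of the simulation rather than defects. First, the downstream demand module
recomputes the category from realized data (realized maximum weekly
throughput rather than nominal capacity), which misclassifies some episodes
exactly as it would on real data — at the default utilisation about 80% of
episodes keep their generative category. Second, and dominant: a high
census is a *real backlog*, and FIFO scheduling under a slot constraint
makes patients admitted into it wait mechanically, so the total demand
effect in queue-generated data is the injected log-shift **plus** the
congestion delay, and fitted percent changes there are far larger than the
injected +5.1/+12.2/+22.0 (roughly +30/+90/+250% at default utilisation).
This is the generator realising "time to surgery is governed by variation
in demand" as an actual queueing mechanism; published effect sizes from
real hospitals — where schedulers react, capacity flexes and the weekly-max
rate proxies deliverable capacity — are much smaller. Quantitative
parameter-recovery checks therefore use the model-based episode sampler
(`simulate_aft_dataset`), where the estimand equals the fitted model by
construction; the queue simulator validates the structural pipeline
(merging, exclusions, census, rates, censoring) and the direction and
monotonicity of demand effects.

A configurable fraction of episodes (default 8.6%, the published transfer
share) is emitted as two abstracts split at a uniform day with a same-day or
next-day gap; splits occur before surgery when the stay allows (setting the
ground-truth preoperative-transfer flag) and after surgery otherwise.
Transfers stay within the same hospital identifier: the analysis assesses
demand at the admitting hospital, and a cross-hospital referral structure is
not part of what the generator emulates. The generator also does not
emulate: mortality or clinical outcomes, ICD coding (flags are born
resolved), hours-resolution timing, competing non-hip-fracture surgical
demand, or real geography. Passing tests therefore validate the pipeline's
statistical machinery, not those aspects of real discharge data.

Everything is driven by one integer seed; fixed seed fixes every output
byte-for-byte.

## Numerical choices and edge cases

- Interval probabilities are computed in the smaller tail via `log_ndtr`
  and a log1p-difference, stable out to extreme z-scores; the analytic
  first/second derivatives used by the mode search are verified against
  finite differences.
- Starting values: least squares on interval midpoints of the log bounds;
  σ floor 0.05; τ start 0.1.
- Degenerate inputs: empty NPMLE input, all-right-censored groups, single
  hospitals with random effects, constant design columns (separation), and
  unseen covariate levels at prediction all raise named errors.
- Ties and boundaries: category boundaries closed on the right; the
  24-surgeries-per-year exclusion is inclusive ("24 or less"); merge gap
  rule inclusive at one day.
- Percentages in tables are rounded half-up to one decimal, and every
  printed percentage is recomputed from the printed counts as an audit.

## Problem sizes

Default test and acceptance runs use scaled-down cohorts chosen as the
smallest sizes at which the checked properties are statistically sharp:
episode-merge recovery on ≈10,000 episodes; parameter recovery over 200
replicates of 200 hospitals × 50 episodes (mean recovered percent changes
within Monte-Carlo error of the +5.1/+12.2/+22.0 truth, CI coverage checked
against its nominal level); the acceptance script simulates 36 hospitals
over 2004–2006 (≈20,000 episodes). The full-scale configuration
(90 hospitals, 2004–2012, ≈150,000 episodes) is the generator default and
runs the same code paths.

## Known limitations

- The random-effects integral treats intercept and slope as independent; a
  correlated or category-wise random-slope design is not implemented.
- Cluster-robust inference relies on a moderate number of hospitals; with
  very few hospitals the sandwich variance is anti-conservative.
- With rare demand categories (the excessive group is ~1.6% of episodes at
  the published mix) the Wald interval on that coefficient rests on ~160
  events per replicate at the recovery-study size; the acceptance suite
  verifies its coverage lies in a band around the nominal level, but exact
  small-sample calibration should not be expected.
- The queueing simulator's FIFO discipline is an assumption of the
  generator only; real hospitals' scheduling discipline is unknown.
- No confidence bands for the NPMLE curves; no AFT families other than
  log-normal; no hours-scale analysis.
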