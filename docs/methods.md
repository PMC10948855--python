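# Methods

## Model and assumptions

The engine is a two-sex, single-year cohort-component projection over
ages 0–100+ with an annual time step anchored at 1 January. Within each
projected year events are ordered survival → births → migration:

* **Survival.** Central death rates m(x, s, t) convert to one-year death
  probabilities by the standard separation-fraction approximation
  q = m / (1 + (1 − a)·m), with a(0) = 0.1 (infant deaths cluster early
  in the interval) and a(x ≥ 1) = 0.5. Survivors of age 99 and of the
  open 100+ interval pool at 100+, the pool using the 100+ rate.
* **Births.** Expected births apply the year's age-specific fertility
  rates to the *start-of-year* female counts — no mid-year exposure
  adjustment. Newborns split by the sex ratio at birth (female share
  1/(1+SRB)) and are exposed to one application of s(0) before the next
  1 January.
* **Migration.** The yearly net total is spread over age and sex by a
  Rogers–Castro family schedule and added at year end: migrants get no
  mortality or fertility exposure in their arrival year, and their ages
  are as of the next 1 January. Cells driven negative by net
  out-migration are floored at zero and the deficit is logged, never
  silently redistributed.

The intra-year ordering and the newborn-survival convention are not
forced by the data; they are isolated in `project_one_year` so an
alternative convention is a one-function change.

Stochastic mode follows the chain with integer counts: per-cell
Binomial(n, s) survivors, Poisson total births around the deterministic
mean, a binomial newborn sex split, and deterministic-in-expectation
migration (below). Randomness comes from numpy `SeedSequence` substreams
keyed by (seed, replicate, year, stage), so replicates are
order-independent, parallelizable, and bit-reproducible.

## Counterfactual construction

The no-shock schedules are rebuilt from unperturbed anchor years of the
baseline, independently per (age, sex) cell with no cross-age smoothing:

| process   | window      | rule                                          |
|-----------|-------------|-----------------------------------------------|
| mortality | 2020–2024   | linear in log m between the 2019 and 2025 anchors |
| fertility | 2020        | TFR = mean of 2019 and 2021 TFRs, on the 2021 age pattern |
| migration | 2020–2021   | linear in the total between 2019 and 2022     |

The sex ratio at birth is never counterfactualized. Anchor years are
keyword parameters with these defaults, so other shock windows reuse the
code. The mortality construction is scale-equivariant and reproduces any
baseline that is already log-linear over its window (null-shock
recovery); both properties are tested.

The decomposition runs the model once per process with only that process
set to counterfactual values, the other two held at baseline. The three
single-component effects need not sum to the joint effect (the processes
interact through births), but do so approximately for small shocks;
near-additivity within 10% is verified under ≤5% perturbations.

## Tunable parameters

* **Rogers–Castro family profile** (both sexes): a1 = 0.02, alpha1 = 0.1,
  a2 = 0.06, alpha2 = 0.1, mu2 = 25 y, lambda2 = 0.4, c = 0.003;
  sex split 0.5. The intensities are dimensionless weights (normalized
  away), mu2 is in years of age, the rate parameters per year of age.
  These place most migration mass in young and working ages, which is
  the substantive assumption; the exact values are a documented,
  replaceable choice, and migration-sensitive outputs inherit their
  uncertainty. The same profile serves baseline and counterfactual.
* **Separation fractions** a(0) = 0.1, a(x≥1) = 0.5 (above).
* **Replicates**: 1000 by default in `run_study`; intervals are
  empirical 2.5/97.5 percentiles (linear interpolation between order
  statistics), not a normal approximation.
* **Horizon**: 2060 by default.

## Synthetic data

The generator emulates the structure of a medium-variant national
projection extract: Gompertz–Makeham mortality (female A = 2.0e-4,
B = 2.6e-5; male A = 3.5e-4, B = 4.2e-5; theta = 0.098) with a
multiplicative 0.5%/yr improvement, so log m is linear in calendar time;
a Gaussian-kernel fertility schedule over ages 15–49 (peak 28, spread
5.5 y) scaled to a TFR path starting near 1.70 and drifting −0.002/yr; a
linear net-migration series at ~0.27% of population per year; SRB 1.05;
and a quasi-stationary pyramid from survivorship weights discounted by
0.8%/yr cohort growth, integerized by largest remainder. The seed
applies a ±1% deterministic jitter to mortality and fertility levels so
distinct seeds give distinct worlds.

The default shock mirrors a pandemic's narrated profile: excess
mortality of 10–60% rising quadratically with age and 4/3 higher for
males in 2020 (80% of that in 2021), a 4% TFR dip in 2020, and halved
net migration in 2020–2021.

Unshocked drafts are *finished through the counterfactual construction
itself*, so within the shock windows they satisfy the interpolation
forms exactly; the default shock leaves the anchor years untouched, and
counterfactual reconstruction from the shocked bundle therefore recovers
the unshocked truth cell-exactly. This converts the inherently
unverifiable counterfactual claim into a parameter-recovery test with no
tolerance ambiguity.

What the fixture does **not** emulate: cohort irregularities (baby
booms), migration age profiles that shift over time, rate forecast
uncertainty, or any calibration to a specific country's vital
statistics. Passing tests therefore demonstrate correctness of the
mechanics and the recovery logic, not numerical agreement with any real
population.

## Numerical choices

* Rates, counts and interpolations are float64 throughout; CSVs are
  written with 17 significant digits so write→read is an exact identity.
* The deterministic bookkeeping identity total(t+1) = survivors +
  surviving newborns + net migrants is asserted inside every step at
  1e-9 relative (before any negative-cell flooring).
* Stochastic-mode migration uses an *unbiased randomized* integerization
  (floor + multinomial allocation of the fractional mass): a
  deterministic largest-remainder rounding would repeat the same ±1
  per-cell error every replicate, biasing replicate means away from the
  deterministic projection by more than the Monte-Carlo standard error
  at small scales. Deterministic mode keeps fractional flows;
  deterministic contexts that need integers (the initial population) use
  largest remainder.
* Initial populations are integerized once, before replication, so all
  replicates share the same starting state.
* Stochastic differences (missing population, dependency changes, share
  changes) pair baseline and counterfactual replicate i via the shared
  substream policy (common random numbers) before summarizing, which
  narrows the Monte-Carlo noise in the differences; medians are barely
  affected by the pairing choice.

## Problem sizes

Tests run on the "tiny" fixture (~10^4 persons); the stochastic-mean
check uses 2000 replicates over a 5-year horizon. The acceptance script
uses the "small" scale (~10^6 persons) with 300 paired replicates to
2060 plus deterministic decomposition runs — at these sizes the whole
study is a matter of seconds, and relative quantities are
scale-invariant in deterministic mode (a tested property), so larger
scales change absolute counts, not rates or percentages.

## Known limitations

* Migration age-sex detail is modeled, not observed; any output that
  loads heavily on migration (notably its share of the long-run missing
  population) is conditional on the schedule parameters.
* Migration is deterministic across replicates, so intervals understate
  total uncertainty; rate-forecast uncertainty is likewise outside the
  intervals.
* Single-region, two-sex model: no parity or education structure, no
  origin–destination migration, no interaction between the shock and
  post-shock rate trajectories.
* The dependency ratios are purely age-based (<15, 15–64, ≥65) and do
  not adjust for labor-force participation.
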