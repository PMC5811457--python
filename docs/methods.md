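# Methods

This note records the models behind `stoichdemo`, the defaults and why
they were chosen, and what the synthetic-data generator does and does
not emulate.

## Trial structure

All analyses assume the three-arm P-supplementation contrast (HP,
LP, LP+P) with algal chemostats as the true unit of replication: every
trait is first averaged per chemostat replicate, and treatment means,
decompositions and bootstrap resampling all operate on those replicate
means. The canonical design is 3 treatments × 5 replicates × 15
individuals for the life table (225 units, one clone), 5 individuals
per replicate for morphometrics (75 units), 3 clones × 3 treatments ×
5 replicates for the 22-day census experiment (45 units), and 2 clones
× 3 treatments × 5 replicates for the pooled elemental samples (30
units of 150 animals each).

## Observation model and event simulation

Individuals are checked on a fixed grid (default every 2 h), so an
event that happens at latent time `t` is recorded at the first check at
or after `t` (rounded *up*: the event is first seen at the subsequent
check). All latent waiting times — maturation, inter-egg intervals,
egg development — are Gaussian around their treatment means, truncated
at zero by redraw; with zero standard deviation they degenerate to the
mean, giving fully deterministic cohorts useful as oracles.

Adult death is a per-check Bernoulli hazard derived from the configured
per-hour probability (`p_check = 1 − (1 − h)^w`), which makes the
latent death time geometric on the check grid. Egg death is a single
Bernoulli draw at laying; the death is recorded at the time the egg
would have hatched, when its failure becomes unambiguous. Each egg is
male with a small probability; a male egg ends monitoring of the mother
(right-censoring), matching the protocol of removing animals that enter
the sexual phase. Monitoring otherwise ends at the hatching of the
fourth neonate (HP, LP+P) or at a fixed 62-h horizon (LP, where
development is too slow for the neonate rule), with a 240-h hard cap.
Eggs laid before but resolving after the end of monitoring are recorded
with fate `unresolved` and excluded from egg-mortality denominators, so
truncation does not bias mortality estimates.

Randomness uses one master seed that deterministically spawns an
independent substream per experimental unit (keyed by generator,
treatment, replicate and unit index). Shrinking the design therefore
leaves the data of every retained unit unchanged, and identical
configurations are byte-identically reproducible.

## Default generator parameters

The trial's absolute trait means are known only graphically, so the
defaults are illustrative rather than calibrated; they were chosen once
to reproduce the qualitative structure of the system: HP fastest
(maturation 22 h, inter-egg interval 4 h, egg development 12 h, no egg
mortality), LP slowest (38 h / 11.2 h / 14.7 h, egg mortality
probability 0.231, per-hour adult hazard 1.34 × 10⁻³), LP+P
intermediate for most traits but tracking LP for egg size and first-egg
development time, and tracking HP for egg survival. Algal molar C:P
centres are the measured 112 (HP), 631 (LP) and 113 (LP+P). Configured
census growth rates are 0.80 / 0.495 / 0.66 d⁻¹ with additive clone
offsets of ±0.03 d⁻¹, inside the range typical of *Brachionus* at
ad-libitum food.

The reported algal C:P standard errors (2.6, 14.9, 2.7) are standard
errors of treatment means. The generator interprets them as arising
from the 25-batch sampling design (5 replicates × 5 occasions), so
per-batch values are drawn with standard deviation `se · √25`; the mean
of a default 25-batch sample then has exactly the quoted standard
error. Pooled elemental masses use a 5% coefficient of variation.

What the generator does **not** emulate: algal physiology (P uptake
kinetics, polyphosphate storage — C:P is sampled, not mechanistic),
sexual reproduction beyond censoring on male eggs, within-clone genetic
variation in life history, density or food-depletion feedbacks in the
census wells, and measurement error in morphometric readings beyond
simple Gaussian scatter. Passing tests on simulated data therefore
demonstrate the estimators' correctness under the stated observation
model, not the biological fidelity of any particular parameter value.

## Life table

`lx` at age class `x` is the fraction known alive entering the class
among individuals not yet censored: censored animals leave the risk set
without counting as deaths, deaths remain in the denominator. This
cohort-proportion definition (rather than a Kaplan–Meier product limit)
matches how a fully-followed cohort is tallied and is non-increasing
under any censoring pattern. `mx` counts *hatched neonates* in the
class per individual at risk there — scoring offspring at hatch rather
than at laying makes egg mortality reduce fecundity exactly as it
reduces population growth. An initial-cohort denominator is available
(`denominator="initial"`); the survivor-based one is the default. The
default class width is the 2-h observation resolution.

Per-individual traits: age at first egg is the first lay time; egg
development time is hatch minus lay per hatched egg; the egg production
rate is total eggs laid divided by the first-to-last lay span and
requires at least two laying events (otherwise flagged unavailable).
Mortality summaries report percentages to one decimal; male and
unresolved eggs are excluded from egg-mortality denominators.

## Growth rates

The intrinsic rate of increase solves `1 = Σ lx·mx·e^(−r·x)` with ages
at class midpoints converted to days. The left side is strictly
decreasing in `r`, so the root is unique; it is found by Brent's method
on a bracket (default ±5 d⁻¹) that doubles automatically when the root
lies outside. The sum is evaluated in log space (`logsumexp`), which
keeps the solver stable even for schedules whose fecundities underflow
ordinary floating-point evaluation near the root. The residual
`|Σ lx·mx·e^(−r·x) − 1|` is reported and must beat the tolerance
(default 10⁻¹⁰). Schedules from horizon-truncated cohorts (LP) are
solved as-is and flagged `truncated`: late-life reproduction outside
the horizon is unobservable, so their `r` estimates carry a truncation
bias that the flag, not a correction, documents.

Census rates average the daily log-ratios `ln Nt − ln N0` over the
final 16 scored days of a 22-day series (days 7–22), the period when
growth has stabilised; days ending at zero are excluded and counted.
The lognormal census noise model makes the daily log-ratio an unbiased
estimate of the configured rate (integer rounding of counts adds a
small bias that the recovery tests bound empirically).

## Decomposition and uncertainty

Relative differences put the comparison baseline in the denominator
(HP for the indirect component, LP+P for the direct one), so the two
components compound exactly: `(1 + i/100)(1 + d/100) = ȳ_LP/ȳ_HP`.
Mortality-type traits are decomposed on survival `1 − m` — the only
convention that keeps denominators nonzero when a treatment reaches 0%
mortality. Scenario classification needs a tolerance because empirical
components are never exactly zero; the default is 5 percentage points
and is user-settable.

Confidence intervals are 95% percentile bootstrap over chemostat
replicates, resampled with replacement independently within each
treatment (default 1000 resamples, seeded). With the canonical five
replicates per treatment, percentile intervals undercover somewhat, as
is usual at such small cluster counts; the coverage test asserts a
correspondingly loose band.

## Numerical conventions

Atomic masses are fixed at C 12.011, N 14.007, P 30.974 g/mol (five
significant figures); consistency across the package matters more than
the fifth digit. Times are stored in hours (census days as integers),
volumes in µm³, pooled masses in µg. Grid placement uses a 10⁻⁹
rounding guard so times that are exact multiples of the check interval
stay on their check. Missing first-egg measurements in morphometry rows
get the replicate-mean egg volume substituted and the row flagged,
keeping per-replicate means estimable; negative somatic growth rates
are returned and flagged rather than raised.

## Problem sizes

The test suite runs the full design (225 individuals, 45 census
series) for structural checks, 1000-individual cohorts for parameter
recovery, and 200–500 bootstrap/simulation repetitions for interval
and coverage checks — sizes at which every Monte-Carlo bound in the
tests is meaningful while the whole suite completes in well under a
minute.

## Known limitations

- Default trait means are not calibrated to any measured dataset;
  analyses of real trials should supply their own tables or override
  the parameter file.
- The LP truncation bias in Euler–Lotka `r` is flagged, not corrected.
- The egg-production-rate interval convention (first-to-last lay) is
  one of several defensible readings of "an interval encompassing at
  least two egg production events".
- No mixed-model or multiple-comparison inference is included by
  design; the exported per-replicate tables feed any such downstream
  analysis.
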