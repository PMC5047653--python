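# Methods

`shoalresp` quantifies the "calming effect" — the reduction in an
individual's metabolic demand attributable to the presence of conspecific
cues — from intermittent-flow respirometry of a small gregarious reef
fish. This note documents the measurement model, the statistics, the
synthetic-data generator that stands in for raw trials, and the numerical
and design choices a maintainer should know about.

## Measurement model

A focal fish sits in a sealed inner chamber (default 0.100 L including
tubing) whose dissolved oxygen is sampled every 2 s by an optode. The
chamber alternates 9-min sealed **measurement** periods with 3-min
**flush** periods that restore oxygen-saturated water; an outer chamber
(1.10 L) can hold shoal-mates that supply visual and olfactory cues
without entering the oxygen balance. During a measurement period,

    d[O2]/dt = -(MO2(t) + B(t)) / V_eff,

where `MO2` is whole-animal oxygen uptake (mg O2 h^-1), `B` bacterial
(background) respiration, and `V_eff = V_chamber - m_fish/ρ` the
effective water volume (fish density taken as 1 g mL^-1; subtraction can
be disabled). Each period contributes one ordinary-least-squares slope of
concentration against time, with the first and last 60 s excluded so the
recirculation loop equilibrates after flushing; windows shorter than
120 s after trimming are dropped. Slopes convert to uptake as
`MO2 = -slope × V_eff` (consumption positive). Fits with r² ≤ 0.97 fail
QC; they are excluded from summary statistics by default but retained,
flagged, in the slope table.

Background respiration is measured in empty chambers for three
measurement periods before and after the trial (fitted with the full
chamber volume). The pre rate is anchored at trial start, the post rate
at trial end, and the correction subtracted from each period's MO2 is the
linear interpolation evaluated at the window midpoint — the midpoint is
unbiased for a linear drift. Negative fitted background rates are clamped
to zero with a warning; corrected MO2 values below zero are floored at
zero with a warning counter.

## Summary statistics

* **MR_min** — the lowest 10th percentile of per-period MO2 over the
  whole trial, computed as the mean of all values at or below the
  empirical 0.1-quantile (at least one value is always included). This is
  the standard low-decile estimator of minimum/standard metabolic rate;
  the interpolated quantile point estimate is available via
  `method="quantile"`. No settling exclusion is applied to MR_min — the
  low decile self-selects quiescent overnight periods — whereas:
* **RMR** — the mean MO2 of periods whose window midpoint falls after the
  first 5 h in the respirometer (the settling exclusion). The asymmetry
  between MR_min (no exclusion) and RMR (5 h exclusion) is deliberate and
  mirrors standard practice for each statistic.
* **ISR** — initial stress response: the first post-transfer period's MO2
  minus MR_min. It uses the background-corrected first slope by default
  (switchable to raw); if the first period fails QC, ISR is reported
  missing with a reason, never imputed.
* **Stabilization time** — the field reports when oxygen consumption
  "settles" but no algorithm, so the detector here is artifact-defined:
  the earliest window midpoint t\* from which the rolling mean of k = 3
  consecutive periods stays within δ = 10% of the final-3-h mean for all
  later windows. It is monotone in δ, returns the trace end flagged
  `unstabilized` when never satisfied, and recovers the generator's true
  settling time within ±0.75 h at low noise.

## Body condition and mass correction

Fulton's condition factor is `K = 100·M/L³` (M wet mass in g, L standard
length in cm). Metabolic rates are mass-corrected by a single pooled OLS
of log rate on log mass across the cohort; each fish's residual is added
to the fitted value at the reference mass (default 1.84 g, the cohort
mean) and exponentiated. Pooling across treatments follows the
one-relationship convention; per-treatment fits are a flag away. When all
masses equal the reference the correction is the identity; when the
reference equals the geometric-mean mass the cohort geometric mean is
preserved.

## Inference

Two routes, deliberately redundant:

1. **Paired sign-flip permutation test** (bespoke, fully self-contained):
   the statistic is the mean of per-fish paired differences
   (solitary-testing minus shoal-testing). All 2^n sign assignments are
   enumerated exactly for n ≤ 12; above that, seeded Monte-Carlo with the
   add-one correction keeps p in (0, 1]. The effect size reported is the
   mean per-fish percent reduction `100·(solitary − shoal)/solitary` —
   per fish first, then averaged, so an individual range is meaningful.
2. **Linear mixed model** (delegated to statsmodels MixedLM): response ~
   holding treatment + testing treatment + body mass, with a random
   intercept per individual. Wald z² statistics (F-type with 1 df) and
   p-values are reported. A singular or failed random-effect fit (e.g. a
   constant response) falls back to fixed-effects-only OLS, flagged.
   Autocorrelation-corrected covariance structures are outside scope and
   noted as such in report output.

Under a zero-effect simulation both routes hold their type-I error near
the nominal 5% (checked at α = 0.05 over 50 replicate cohorts).

## The synthetic-data generator

No raw traces are distributed, so the generator *is* the study material:
it emulates the full measurement chain with known truth so every pipeline
stage is testable by parameter recovery. Per fish,

    MO2(t) = F·(m/m_ref)^b · s(c)  +  A·(m/m_ref)^b · exp(-t/τ)  +  a_p,

with `F = 0.35 mg O2 h^-1` the solitary metabolic floor at the reference
mass `m_ref = 1.84 g`, allometric exponent `b = 0.89`, `s(c) = 1` for
solitary testing and `1 − e` for shoal testing, where the per-fish effect
`e ~ 0.05 + 0.55·Beta(2, 3.263)` has mean 0.259 on [0.05, 0.60] —
matching the reported mean 25.9% reduction and 5–60% individual range.
The handling-stress amplitude `A = 0.25 mg O2 h^-1` and decay constant
`τ = 2.34 h` are set so the true settling time `τ·ln(A/(0.1·F)) = 4.6 h`.
Activity noise `a_p ~ N(0, 0.01 mg O2 h^-1)` is one draw per measurement
period (biological), truncated so total uptake stays non-negative;
instrument noise is white per-sample optode noise (sd 0.004 mg L^-1).
The floor magnitude is a realistic routine-rate scale for a ~2 g
damselfish at 29 °C and, together with the chamber geometry and cycle
timing, keeps every sample above 80% air saturation; the optode noise sd
is chosen jointly with the 0.97 QC floor so that default-noise window
fits clear it — these two defaults are coupled by construction and should
be moved together.

Background respiration drifts linearly from 0.002 to 0.010 mg O2 h^-1
across the trial (1–3% of the fish signal). Trials run 11.5 h. Measure
phases integrate the mass balance in closed form (no ODE solver error);
flush phases relax exponentially toward saturation with a 40 s time
constant — chosen to exceed 99% saturation within the 180 s flush — minus
a small consumption-equilibrium deficit. Air saturation uses
6.236 mg L^-1 at 29 °C / 35 ppt (García–Gordon fit), exposed as an
overridable constant.

Morphometrics: masses N(1.84, 0.12²) g, lengths N(3.69, 0.09²) cm.
Solitary-held fish lose 5% wet mass between weeks 0 and 1 (shoal-held
fish do not), reproducing the condition-factor divergence; weekly
multiplicative growth noise has sd 1%.

Everything is seeded: a trial's random stream derives from
(config seed, fish id, testing condition), so paired trials share their
fish-level truth and identical calls are byte-identical.

### What the generator does not emulate

Real optode drift and temperature fluctuation; diel activity rhythms and
spontaneous activity bursts (activity noise is white, not autocorrelated);
behavioural interaction with shoal-mates (the outer chamber acts only
through the effect multiplier); chamber mixing dynamics. Passing
parameter-recovery tests therefore demonstrates that the pipeline is
correct and well-calibrated for this generative model, not that any
particular biological effect size would be recovered from field data.

## Numerical choices and degenerate inputs

- r² for a zero-variance (flat) window is defined as 0 and the fit fails
  QC: a flat trace carries no rate information. Identical timestamps
  raise a singular-fit error.
- Phase intervals are half-open `[start, end)`; a sample exactly on a
  transition belongs to the later phase.
- MR_min requires ≥ 10 QC-passing periods; RMR requires ≥ 1 period after
  the cutoff; the stabilization detector requires ≥ 3 h of data. Each
  raises a named insufficient-data error otherwise.
- The permutation p-value comparison uses a 1e-12 relative tolerance when
  counting null statistics at least as extreme as the observed one, so
  enumeration ties are not lost to floating-point rounding.
- Problem sizes used by the verification scripts — 5 seeds × 16-fish
  cohorts for effect recovery, 10 trials for the QC floor, 5 for the
  saturation bound, 50 replicate cohorts for inference calibration — give
  Monte-Carlo standard errors comfortably inside the tolerances they are
  checked against.

## Known limitations

- The mixed model reports Wald (z-based) inference, which is mildly
  liberal at n = 16 individuals; the permutation test is the
  finite-sample-safe path.
- The decile-mean MR_min is slightly biased below the true floor in the
  presence of activity noise (order 1.5 sd of the per-period noise); the
  bias largely cancels in the paired percent-reduction contrast because
  it is common to both testing conditions.
- Background correction assumes the empty-chamber rate transfers
  unchanged to the occupied chamber and grows linearly in time.
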