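# Methods

`cmparams` summarizes a patient's complete longitudinal record of a
clinical measurement (CM) — a vital sign or laboratory analyte — into 13
scalar parameters organized by seven clinical attributes, and feeds the
resulting candidate set into logistic models of short-term mortality.
This note documents the model and its conventions, the synthetic cohort
the package ships for end-to-end testing, the numerical choices, and
the known limitations.

## The parameter synthesis

Input is a per-patient, per-CM series of `(day, value)` readings at
irregular visit times, together with a *treatment target* declaring
which values are abnormal: strictly below a low bound, strictly above a
high bound, or either (two-sided targets such as hematocrit).  Values
exactly at a bound are normal.  Time has whole-day resolution; if a day
carries several readings the last-entered value is kept and the
collision logged.  Records are truncated at the index date minus a
blackout (default 14 days) so that readings from the pre-symptomatic
phase of the index illness never enter the summary.  BMI is derived
from weight and the most recent prior height (forward-filled; height is
quasi-static).

Successive reading pairs are classified four ways: abnormal→abnormal
spans are *not at goal*, normal→normal *at goal*, normal→abnormal
*worsening*, abnormal→normal *improving*.  Worsening/improving spans
belong to neither at-goal nor not-at-goal time.

The 13 parameters, by attribute:

| attribute | parameter | definition |
|---|---|---|
| current control | `Value1` | most recent value |
| chronicity | `FUDaysNotAtGoal` | days summed over not-at-goal pairs |
| | `NumNotAtGoal` | count of abnormal readings |
| disease burden | `AbnAUC` | trapezoidal area of the excess beyond the target (unit·days) |
| | `TimeWtAvg` | trapezoidal AUC / days of follow-up |
| refractoriness | `TimeNotAtGoal` | duration of the currently open abnormal cluster |
| | `CtNotAtGoal` | reading count of that cluster |
| | `MaxClustDays` | longest duration over clusters with ≥ 2 readings |
| relapse | `NumClust` | number of abnormal clusters |
| lability | `CoeffVar` | sample SD / grand mean |
| | `MeanValDiff` | mean absolute successive difference |
| trends | `NetChange` | last minus first value |
| | `Lag3Dev` | (last − mean of 3 preceding) / mean of 3 preceding |

A *cluster* is a maximal run of consecutive abnormal readings.  Three
conventions resolve questions the verbal definitions leave open:

* an abnormal **first** reading opens a cluster (always-abnormal
  patients have clusters too);
* an **open** (unterminated) run counts toward `NumClust`, and the
  refractoriness pair (`TimeNotAtGoal`, `CtNotAtGoal`) describes exactly
  that open run — patients whose most recent reading is normal have no
  open run and carry missing values there;
* cluster duration runs from the first to the **last abnormal** reading
  of the run: the terminating normal reading's day belongs to the
  improving interval, which is classified separately.

Missingness is explicit (`None`/NaN, never a sentinel): span-based
parameters (`FUDaysNotAtGoal`, `AbnAUC`, `TimeWtAvg`, `CoeffVar`,
`MeanValDiff`) require ≥ 2 readings; `MaxClustDays` requires a cluster
of ≥ 2 consecutive abnormal readings; `Lag3Dev` requires exactly 3
lagging values (n ≥ 4) and a nonzero lagging mean — it is not computed
on a shorter window; `CoeffVar` requires a nonzero grand mean.
`NetChange` is 0 for a single reading (most recent = first).

Areas use endpoint trapezoids with **no** interpolation, extrapolation
or curve fitting.  For `AbnAUC` the excess
`e(v) = max(v − high, 0) + max(low − v, 0)` is evaluated at the readings
only; a segment that crosses the bound contributes a half-triangle
based on endpoint excesses, not the geometric crossing point.  This
keeps the summary an exact functional of the recorded readings.

`TimeWtAvg` divides the **full** AUC by total follow-up days, which is
the conventional time-weighted mean of the measurement and is the
quantity invariant to sampling density; dividing the abnormal area
instead is exposed as a configuration switch (`time_wt_avg_on =
"abn_auc"`).  The invariance is exact at the level tested: inserting
readings that lie on the line segment between two visits leaves
`TimeWtAvg` unchanged while moving the raw mean toward the densely
sampled side — precisely the bias created by measuring a CM more often
while it is abnormal.

Two computation paths exist and are contractually identical (exact on
counts/days, 1e-9 relative on reals): an incremental running summary
updated per reading (constant memory; Welford's online mean/M2
recursion for dispersion, so no catastrophic cancellation), and batch
recomputation from the full series.  A third, group-vectorized path
(`tabular.derive_table`) computes whole cohorts with `np.reduceat` and
is tested cell-by-cell against the per-series engine.

### Units and the albumin caveat

The engine is unit-agnostic; targets declare the units.  The shipped
default targets (SBP > 140 mmHg, DBP > 90 mmHg, O2Sat < 95%, BMI > 30,
eGFR < 60 mL/min/1.73m², Alb < 3.5 g/dL, HCT outside 38–52%,
ALT > 40 U/L, A1c > 7%, HDL < 40 mg/dL, LDL > 130 mg/dL) are
documentation defaults, all overridable.  `Alb` is interpreted as
**serum albumin** (low-side target, g/dL); sources that track
albuminuria instead should supply a high-side target in their own units
— nothing else in the engine changes.

## The synthetic cohort

No patient-level data ship with the package; the generator produces
cohorts with the structure the method assumes.

Per CM, a patient's latent value is `baseline + drift·t + excursions`:
baseline ~ Normal across patients, drift a patient-level linear slope,
and excursions an alternating-renewal relapse process (exponential gaps
at the relapse rate; exponential durations; Gamma(2)-distributed
magnitudes pushed toward the abnormal side of the target).  Measured
values add independent Gaussian noise and are clipped to physiologic
ranges.  Visits follow an inhomogeneous Poisson process: candidates at
`base_rate × multiplier` are thinned to `base_rate` while the latent
value is normal, so the realized rate is `multiplier`-fold higher while
abnormal (default multiplier 3) — the informative-observation pattern
that biases the raw mean.  Vitals default to 4 visits/year, chemistries
2, lipids 1.5; follow-up is uniform on 3–10 years; each CM is entirely
absent for a patient with probability `missing_cm_prob` (default 0.05).
Population scales (e.g. SBP 125 ± 12 mmHg, A1c 6.3 ± 1.0%) describe an
older, chronically ill primary-care population.

The binary 60-day mortality outcome is drawn from a logistic model on
the patient's **derived** parameters — the engine applied to the
generated series — so recovery tests are well-posed against the
engine's own definitions.  The linear predictor centers each parameter
at a stated reference; a missing parameter contributes 0 (sits at its
reference), which keeps the outcome defined for every patient while
complete-case fits on the true columns remain exactly specified.  The
default scenario carries six nonzero coefficients spanning five
attributes (`O2SatValue1` −0.20, `SBPTimeWtAvg` +0.035, `A1cNumClust`
+0.22, `eGFRTimeWtAvg` −0.022, `HCTCoeffVar` +9.0, `LDLNetChange`
+0.012; roughly 0.35–0.45 log-odds per population SD each) and an
intercept of −3.4, giving ≈ 5.5% mortality and a true-predictor AUROC
≈ 0.77.  These are the package's chosen study conditions, not estimates
from any cohort.  Covariate effects (age, comorbidity scores) default
to zero so the parameter-only main model is correctly specified;
scenario configurations can switch them on.

What the generator does **not** emulate: correlation between CMs within
a patient, treatment feedback (an abnormal value triggering an
intervention that changes the trajectory), missingness that depends on
health state, competing risks, or calendar-time effects.  Passing tests
therefore demonstrate the correctness of the derivation and modeling
machinery under irregular, informative sampling — not that the shipped
effect sizes generalize to any real population.

## The prediction pipeline

The design matrix holds one row per patient and 13 × 11 = 143 candidate
columns named `<CM><Parameter>` (CM-major, attribute order within CM),
plus the outcome and baseline covariates.  Missing parameters propagate
as missing cells; fits use case-wise deletion over the columns of the
model being fit.

*Subset models*: per CM, the outcome is regressed on that CM's 13
parameters (maximum-likelihood logistic); the in-sample predicted
probabilities give the subset AUROC.  Non-convergence (separation,
singular information) is detected and reported, never silently ignored.

*Main model*: set-wise stepwise logistic regression.  Attribute sets
enter in the order current control, chronicity, disease burden,
refractoriness, relapse, lability, trends (configurable, but entry must
start with the most recent values).  Each whole set is entered, the
model refit, and terms with Wald p ≥ α (default 0.05) removed one at a
time — largest p first, refitting after each drop — before the next set
enters.  "Significant" means the covariate-adjusted Wald p-value from
the multivariable fit; no multiplicity adjustment is applied.  The
final model's predicted probability per patient is `PDeathLabs`.

Because `TimeNotAtGoal`/`CtNotAtGoal` exist only for patients currently
abnormal in that CM and `MaxClustDays` only for patients with a
multi-reading cluster, joint complete cases over all 143 candidates are
essentially nonexistent in any realistic cohort.  The stepwise builder
therefore excludes candidates missing in more than `max_missing_frac`
of rows (default 0.25) before deleting case-wise over the survivors.
In simulated cohorts missingness is strongly bimodal — ≈ 5% for ten of
the parameters versus 33–90% for the three refractoriness parameters —
so any threshold between those bands selects the same columns; the
exclusions are reported with the fit.  Keeping the analysis set fixed
across stages makes p-values comparable between stages.

*AUROC*: computed as the Mann–Whitney concordance (ties one half), with
DeLong standard errors from the empirical variance of the placement
values; curve comparisons use the paired DeLong test (covariance of
placements) or the unpaired normal approximation.  Evaluation is
in-sample, matching a development-only design; note that the in-sample
AUROC of a fitted model is optimistic — under a null outcome, a
13-parameter fit at ~20 events per variable shows in-sample AUROC near
0.55 while its held-out AUROC is 0.5 within Monte-Carlo error.  The
test suite checks null discrimination on held-out halves for exactly
this reason.  Single-factor baselines (age, 2-year/lifetime Charlson,
2-year/lifetime Elixhauser) are one-predictor logistic fits; their
AUROC equals that of the raw covariate by monotone invariance.

## Numerical and implementation notes

* Degenerate inputs: empty series yield an all-missing vector;
  single-class outcomes, constant covariates and zero complete cases
  raise explicit errors; reversed reading order signals an upstream
  sorting bug rather than being silently reordered.
* Ties in the backward-removal step are broken by column order (the
  first of equal worst p-values is dropped); p-values are compared
  strictly (`p ≥ α` removes), so α = 1.0 retains everything.
* All simulation randomness flows from one integer seed through numpy
  `SeedSequence`; identical seeds give byte-identical cohorts.  The
  generator is vectorized column-wise (per CM across patients), so
  reproducibility is per-seed, not per-patient substream.
* Problem sizes used by the shipped verification suite: the
  incremental/batch contract is checked on 1,000 random series; the
  oversampling-invariance property on 100 generated series; recovery
  and null behavior on 20 replicates of n = 20,000 patients each
  (≈ 5 × 10⁶ readings per replicate), sizes at which every
  population-level check has comfortable Monte-Carlo margin.

## Limitations

The package implements a development-only analysis: no train/test
split, calibration assessment, or optimism correction is applied to the
reported AUROCs (the null-behavior tests quantify the optimism to
expect).  The stepwise procedure inherits the usual caveats of stepwise
selection — inflated per-term error rates and post-selection p-values
that are not confirmatory.  Charlson/Elixhauser scores are consumed as
given covariates, never computed from diagnosis codes.  The engine
processes one CM at a time; cross-CM features (ratios, joint
trajectories) are out of scope.
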