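# Methods

## The burden statistic

A patient's lactate curve is reconstructed from serial draws as the
piecewise-linear interpolant of (time, value) pairs within an observation
window, by default the first 24 h of the ICU stay. The window boundaries
are filled by constant extrapolation — the value at the window start is
defined equal to the first observed value, the value at the window end
equal to the last observed value within the window — after which the
**lactate load** is the exact trapezoidal area under the curve
(mmol·h/L) and the **normalized lactate load (nll)** is the load divided
by the window duration (mmol/L). Reported alongside are the maximum and
the unweighted mean of the observed values; the mean is deliberately not
time-weighted, since the time-weighting is what distinguishes the
normalized load from it.

Ingest rules, chosen here because extraction conventions are rarely
stated in source data: draws before the window start (pre-ICU samples)
or after the window end are dropped with a logged count; exact-duplicate
timestamps are averaged, making the curve a well-defined function of time
and the result invariant to row order. The window is configurable; all
statistics are invariant under a common time translation of the data and
the window.

Degenerate inputs: a patient with no draw inside the window raises
`NoMeasurementsError`; a single draw yields a constant curve, so
max = mean = nll = that value. Values must be positive (lactate is a
concentration); non-finite inputs are rejected rather than silently
dropped.

## Eligibility cascade

Four exclusions are applied sequentially, each patient counted at the
first criterion it fails: age < 18 years; not the first ICU admission;
fewer than two lactate measurements in the window (zero included); ICU
stay shorter than 24 h. The order is fixed for reproducibility; totals
satisfy `screened − Σ excluded = included` by construction, and
re-applying the cascade to an included cohort excludes nobody. The sepsis
flag is a supplied adjudication (an input column), not derived here.

## ROC machinery

The AUC is the Mann–Whitney statistic with half credit for ties —
exactly the estimator DeLong variance theory presupposes. Placements
(structural components) are computed with midranks in O(N log N):
for positive i, `V10_i` is the tie-corrected fraction of negatives it
exceeds; symmetrically `V01_j`. Then `var(AUC) = S10/m + S01/n` with
sample variances of the placements, and paired comparisons add the
placement covariances. Choices the source conventions leave open, fixed
here as the simplest defensible ones:

* AUC confidence interval: Wald on the probability scale, truncated to
  [0, 1]; degenerate (auc, auc) when the variance is zero (perfect
  separation).
* Marker orientation: higher value ⇒ higher predicted mortality risk,
  always; no automatic direction detection.
* Cutoffs: Youden's J maximised over the observed score values under the
  "positive if score ≥ cutoff" convention, ties broken toward the
  smallest cutoff.
* Operating characteristics at a cutoff: Clopper–Pearson (exact binomial)
  intervals for sensitivity, specificity, PPV and NPV (predictive values
  at the observed prevalence); log-method intervals for likelihood
  ratios. A likelihood ratio with a zero denominator is reported as
  infinite with an undefined bound and logged, rather than silently
  clipped.
* Degenerate comparisons: zero variance with equal AUCs gives z = 0,
  p = 1; with unequal AUCs it is an error.
* CI level 0.95 and two-sided α = 0.05 throughout.

## Baseline-table statistics

Continuous variables pass through a Kolmogorov–Smirnov normality gate
against a normal with the sample's estimated mean and SD at α = 0.05
(estimated parameters, i.e. Lilliefors-flavoured usage, matching common
clinical practice; n < 3 or constant samples are treated as non-normal
rather than crashing). Variables normal in both cohorts are summarised
mean ± SD and compared by Student's t-test; otherwise median (IQR) and
Wilcoxon rank-sum. Categorical variables use Pearson's chi-square without
continuity correction. No multiplicity correction is applied — the table
is descriptive.

## Synthetic cohort generator

The generator emulates the data-generating reality the statistic is
meant to summarise; it is explicitly a stand-in, not a model of any
particular database.

**Trajectory.** Each patient has a latent noiseless curve
`Lac(t) = b + (L0 − b)·exp(−k t)`: initial lactate `L0`, physiological
baseline `b = 1.0` mmol/L, clearance rate `k` (1/h). Its exact time
average over the window — `b + (L0 − b)(1 − e^{−kT})/(kT)`, or `L0` at
`k = 0` — is the *true* normalized load.

**Sampling.** The number of draws is `max(min_count, 1 + Poisson(λ − 1))`
with per-patient intensity λ; draw times are `24·Beta(0.7, 2.0)`,
i.e. clustered early, reflecting dense sampling during early
resuscitation. Early-skewed times are also what make time-weighting
informative: an unweighted mean of early-clustered draws over-represents
the pre-clearance phase, while the trapezoid does not. Observed values
add N(0, σ²) noise (σ = 0.2 mmol/L, emulating assay error plus
short-term physiological fluctuation) and are floored at 0.1 mmol/L.

**Outcome.** 28-day death is Bernoulli with
`logit p = β0_group + β1 · true nll`, so mortality is driven by the true
burden and every observed marker is a noisy surrogate of it. The maximum
essentially estimates `L0` (it ignores clearance entirely), the
unweighted mean sits in between, and the observed nll is the best
surrogate — hence the expected AUC ordering nll ≥ mean ≥ max, which the
acceptance suite checks on the default cohort.

**Defaults** (per group: non-sepsis / sepsis), chosen once to echo the
qualitative contrasts of large ICU cohorts — higher initial lactate,
slower clearance, denser sampling and higher mortality in sepsis —
without claiming numerical fidelity to any database:

| parameter | non-sepsis | sepsis |
|---|---|---|
| L0 ~ LogNormal(meanlog, sdlog) | ln 2.8, 0.4 | ln 3.6, 0.5 |
| k ~ LogNormal | ln 0.12, 1.2 | ln 0.05, 1.2 |
| λ ~ LogNormal | ln 2.2, 0.7 | ln 6.0, 0.5 |
| β0 | −3.6 | −3.0 |

with β1 = 0.9 per mmol/L, p(sepsis) = 0.2 and n = 20,000 patients.
Under these defaults roughly half the screened cohort survives the
eligibility cascade, group mortality is ≈ 36% / 13%, and the nll AUC is
≈ 0.77 (sepsis) / 0.68 (non-sepsis). Ineligible records are planted at
configurable rates (1% minors, 10% repeat stays, 13% short stays; single
draws arise naturally from the count model) so the cascade is exercised.
All randomness flows from one `numpy.random.Generator` seeded in the
config; output tables are bit-reproducible given the seed.

**What the generator does not emulate.** Treatment feedback (sampling
intensity and clearance responding to measured lactate), informative
LOS/censoring, competing risks, non-exponential kinetics (rebounds,
secondary surges), inter-assay drift, and any covariate structure beyond
the sepsis split. Passing tests therefore demonstrate the pipeline's
statistical machinery and the qualitative mechanisms — not that real
cohorts will show the same effect sizes.

**Sampling-density mechanism.** Within a group, draw count varies with
the per-patient λ but is independent of severity, so stratifying on
count ≥ k selects better-estimated curves without selecting on outcome.
In the sparsely sampled non-sepsis group, estimation error is a material
part of the observed nll's variance, so the AUC of observed nll rises
with the count stratum; in the densely sampled sepsis group it is already
near the true-nll ceiling and stays flat. The acceptance check allows
each step a one-combined-SE tolerance (DeLong variances of the two
strata), a conservative allowance given that nested strata are positively
correlated.

## Problem sizes and tolerances in the test suite

Quadrature comparisons use a 1e-4-h grid augmented with the interpolation
knots and a 1e-6 mmol·h/L tolerance; AUC and Youden checks against
enumeration are exact (1e-12). Type-I-error simulations use 2,000
replicates at 200 positives/negatives and accept rejection rates inside
the central 99% binomial band around 0.05; the bootstrap comparison uses
2,000 resamples at 500/500 with a 10% relative tolerance on the SE. The
pipeline-level properties run on one default cohort of 20,000 generated
patients (≈ 10,500 after exclusions). The default `pytest` run completes
in well under a minute on a single core.

## Known limitations

* The boundary-extension rule biases the load upward for patients whose
  last draw is early and falling (the tail is held flat); this is
  inherent to the definition, not an implementation artifact.
* DeLong inference is asymptotic; with very few deaths in a stratum the
  Wald CI can be anti-conservative near 0 or 1 (it is truncated, not
  logit-transformed).
* The KS gate with estimated parameters is anti-conservative as a formal
  normality test; it is used as a summary-style selector, as is common in
  clinical baseline tables.
* `mean_lactate` and `max_lactate` are computed from observed draws only;
  no imputation or kinetic modelling (clearance %, time-to-normalisation)
  is offered.
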