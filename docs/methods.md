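# Methods

## Model

The package implements a cost-minimization model: it assumes the day-2
case-audit leaves clinical outcomes equivalent (readmissions showed no
significant difference in the reference evaluation and are reported but
never modelled) and asks only whether the audit's cost is recovered. Per
audited patient,

    net_benefit = p_drg · (Δlos·c_bed + p_iv·Δnurse·c_nurse/60 + Δab)
                  − c_audit · n_audit

All savings channels are restricted to the infection-DRG share `p_drg`
because patients admitted for severe underlying disease are assumed not to
respond to antibiotic-therapy optimisation; the audit cost, by contrast, is
paid for every audited patient. Nursing time is in minutes against an hourly
wage, hence the /60. The model is affine in every delta and in the audit
price, which the tests exploit: the break-even audit price
`c_audit* = p_drg·(bracket)/n_audit` and the PSA's expectation have closed
forms that the numerical paths must reproduce exactly.

Deltas are control-minus-intervention means, so harm (negative deltas) flows
through as negative net benefit; nothing is clamped.

### Significance gating

A delta enters the point estimate only when its two-sided test yields
p < α = 0.025. The threshold is the study design's fixed familywise
correction for analysing two DRG subgroups; it is deliberately *not* a
generic Bonferroni over outcomes. Default outcome→test mapping: LOS →
log-rank on time-to-discharge (discharge as the event, no censoring
modelled — a documented simplification, since no censoring information
exists in the cohort schema), IV nursing time → Welch t, antibiotic cost and
age → Mann-Whitney U, sex/readmission → Pearson chi-square. The mapping is
user-configurable because reasonable analysts differ here; both log-rank and
Welch routes are first-class for LOS. Identical samples short-circuit to
delta 0, p = 1 (zero-variance inputs would otherwise produce NaN
statistics).

Group summaries use t-quantile 95% CIs (df = n−1) rather than 1.96 — the
per-group ns are small enough that this is the defensible default, and
immaterial at the reference sizes. The IV-nursing denominator is IV-treated
patients only. Records missing an outcome value are dropped listwise for
that outcome with a logged count.

### Calibration outputs

`extract_parameters` returns one `ModelParameters` per DRG group: `p_drg` is
that group's share of the audited cohort, `n_audit` that group's mean
consultations (1.11 / 1.09 in the reference table; the cohort-wide 1.09 is
available as a config override — the two are an internal inconsistency of
the reference report, so both are kept, per-group being the default).
`CalibrationResult.combined_per_patient_net_benefit` sums the groups'
share-weighted brackets and charges the audit cost once.

### Frequency matching

The historic pool is filtered to the intervention arm's DRG-code mix by
largest-remainder apportionment of the target size over the reference code
frequencies, then seeded sampling without replacement within each code.
Largest remainder guarantees every per-code count is within 1 of its ideal
real-valued target; ties in fractional parts resolve to the
lexicographically earlier code.

## Uncertainty analysis

**Surfaces.** `sensitivity_surface` evaluates the model over a linear grid
(endpoints inclusive) of any two parameters, plus a derived axis mapping a
fractional LOS reduction onto `delta_los` via the baseline control LOS. Axis
values must respect parameter domains; violations raise rather than clip.

**PSA.** The probabilistic sensitivity analysis samples the *arm means* of
LOS, IV nursing time and antibiotic cost — intervention and control
independently by default — recomputes each delta per draw, and evaluates the
model with every other parameter fixed. Defaults and their rationale:

* **Family: normal on the means, SE = CI halfwidth / 1.96.** Group means at
  these ns are close to normal by CLT, and the reported interval halfwidths
  are the only spread information available. Gamma and lognormal
  (moment-matched) are offered for skew-sensitive analyses, and a
  direct-difference mode (delta ~ one distribution with pooled SE) exists;
  under independence both modes have identical first two moments.
* **Antibiotic cost participates in the PSA even though it is gated out of
  the point estimate** — the gate encodes a hard decision rule, while the
  PSA is exactly the place to represent that effect's uncertainty.
* **No truncation** of sampled means: negative deltas are legitimate
  realisations.
* **p_drg defaults to 1.0 in the packaged PSA configuration**: the question
  asked is the audit's value for a responsive (infection-DRG) patient; the
  group-mix dependence is a deterministic sweep on the surfaces.
* Percentiles use linear interpolation (`numpy.percentile` default); the
  convention is fixed so intervals are comparable across runs.
* Seeds: one integer seeds a `numpy` PCG64 generator; quantity order in the
  spec fixes the draw order, so identical seed + spec is bit-identical.

A known limitation: under the default normal-independent scheme the draw
distribution is symmetric. The reference evaluation's published PSA shows a
clearly asymmetric spread (its minimum sits just above zero while the
maximum reaches nearly three times the median), which no normal scheme can
produce; its exact sampling scheme is unstated. Consequently this package's
95% interval reaches further down (2.5th percentile around EUR 300 at the
reference calibration) than the published lower bound, while median and
upper bound agree closely. The lognormal/gamma families are the provided
route for analysts who prefer a bounded, right-skewed representation.

## Synthetic cohorts

The generator emulates the *structure* the calibration consumes: two arms ×
two DRG groups with configurable outcome distributions. Choices:

* LOS ~ gamma (positive, right-skewed — the stylised shape of hospital
  stays), parameterised by mean and SD;
* IV nursing minutes ~ normal truncated at 0, with the location solved
  (Brent root-find on the truncated-normal mean) so the post-truncation mean
  equals the configured mean — naive truncation would bias means upward by
  several percent at the reference CVs;
* antibiotic cost ~ lognormal (heavily right-skewed: mostly cheap generics,
  a few expensive courses; reference CVs are ~1.5–1.9);
* consultations = 1 + Poisson(mean−1), so every audited patient has ≥ 1
  audit; IV treatment, sex, readmission ~ Bernoulli; ages normal, clipped to
  [18, 105] (ages never enter the model).

Individual-level SDs are backed out of reported CI halfwidths as
SD = hw/1.96·√n. The fixed fixture (`table1_fixture`, seed 1234) additionally
pins arm/group/IV counts to their expected values and rescales each positive
outcome sample to hit the configured mean exactly, so its summary table
reproduces the reference means while individual variation stays realistic.
What the fixture does *not* emulate: within-patient correlation across
outcomes, true LOS/cost distribution shapes (only first and second moments
are honoured), seasonal or policy drift in the historic window, and the
unknown real DBC code vocabulary (a synthetic 4+4-code vocabulary with a
geometric mix stands in). Passing tests therefore demonstrate correctness of
the *pipeline arithmetic and inference machinery* on distributionally
plausible data, not fidelity to any real ward.

## Numerical and testing choices

* All arithmetic at double precision; monetary rounding to cents happens
  only in reports.
* Hypothesis-test p-values are cross-checked against a hand-rolled
  full-enumeration permutation oracle at small n (exact agreement for
  Mann-Whitney without ties; approximate, by construction, for Welch).
* Null-calibration of the gate uses 200 replicate cohorts of 500 patients
  per arm with identical arm distributions; the inclusion rate per outcome
  is checked against a wide (99.9%) binomial band around α.
* Parameter recovery is assessed as replicate-averaged bias (60 replicates
  at 300/arm, 30 at 1200/arm): at realistic outcome SDs a *single* cohort of
  300/arm has a LOS-delta standard error of ≈ 0.40 days against a true
  effect of 1.37, so a one-draw 10% criterion would be a coin flip; the
  averaged estimate is the quantity that actually converges.
* Simulation sizes throughout (200 null replicates, 60+30 recovery
  replicates, 2500-draw PSAs, 50k-draw convergence check) were chosen so the
  whole suite completes in well under a minute while keeping Monte-Carlo
  error far below every asserted tolerance.

## ROI

`roi` implements benefit ÷ cost and nothing else. The reference report's
printed ROI of 5.9 cannot be reconstructed from any cost total it states
(total benefit over implementation cost gives 3.4; over the year's audit
costs, 6.05); the denominator definition is ambiguous, so the package
validates the operation on constructed inputs and reports ROI against both
the audit-cost total and, when configured, a user-supplied implementation
cost (the reference figure of EUR 17,732 ships as an input constant that is
never recomputed).
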