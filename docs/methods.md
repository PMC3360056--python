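# Methods

## Scope and model

The package implements a trial-based cost-effectiveness analysis (CEA)
alongside a 6-month, cluster-randomized, two-arm trial in residential
homes, from a societal perspective. The estimand is the incremental
cost-effectiveness of multidisciplinary integrated care versus usual
care on three outcomes: a quality-of-care indicator sum score (percent
of applicable indicators present, lower = better), COOP WONCA
functional-health change, and QALYs. Analyses are intention-to-treat
with the study's pragmatic exclusions: residents who provided no
baseline data or died during follow-up are excluded from the main
analysis (a sensitivity mode re-includes them).

Clustering (randomization at home level) is deliberately ignored in the
*analysis*, mirroring the original evaluation; the generator still
plants between-home random intercepts so the consequences of that
choice are visible. Home-level bootstrap resampling is available as a
flag for methodological comparison, not as the default.

## Outcome construction

* **Quality-of-care sum score** = 100 × (indicators present) /
  (indicators applicable), unweighted by default with an optional
  per-indicator weight vector. A resident with zero applicable
  indicators gets an undefined (NaN) score and is flagged rather than
  erroring; such residents contribute nothing to this outcome.
* **COOP WONCA** totals sum six ordinal charts (1–5). Arm comparisons
  use baseline-to-follow-up *change* scores: baseline totals sit near
  18 in both arms, so the small arm-level values in the effects table
  are only interpretable as changes. This is a package convention,
  chosen because it is the only scale on which the reported arm values
  (≈ 0.65–0.85) are coherent with baseline totals of ≈ 18.
* **QALYs** integrate the SF-6D utility trajectory by the trapezoid
  rule (health-state transitions linearly interpolated); a constant
  utility u over T years gives exactly u·T. Utilities are accepted as
  inputs; the SF-12-to-SF-6D tariff itself is out of scope and treated
  as a pluggable mapping. In the decedent-inclusive sensitivity mode,
  a decedent's utility falls linearly to zero at death and stays zero;
  lacking death dates, death is placed at the follow-up midpoint
  (0.25 years).

## Costing

Resource-use records (visits, admissions, hours) are valued against a
2007 Dutch unit-price table packaged with the module. Per-record
valuation is computed in integer cents (quantity × price rounded
half-up), so per-patient category totals and the grand total are
exactly additive with no float drift. Medication costs are accepted
pre-costed (unit price 1) or as priced quantities. CPI adjustment is a
configurable multiplicative factor. Productivity costs are structurally
excluded: this is an admitted population.

Intervention costs are top-down: annual components (organizational,
staff training, assessment performance, multidisciplinary meetings —
summing to €13,113) proportioned to the trial period and divided over
the residents of the intervention homes. The published per-patient
figure of €225 cannot be reconstructed from those printed inputs for
any plausible divisor (e.g. 13,113 × 0.5 / 230 ≈ €28.5), so the
allocation inputs are explicit configuration and the packaged study
calibration instead *sets* the observed per-patient margins (€225
intervention, €23 for costed usual-care meetings — not zero, since
multidisciplinary meetings are part of usual care). The license-only
sensitivity mode masks the component set down to the assessment
licensing/subscription component and zeroes the usual-care meeting
column.

## Missing data

Dropout in this population is selective, so missing cost components and
effect measures are multiply imputed (m = 5 by default) by chained
equations with predictive-mean matching (PMM), pooled by Rubin's rules
(T = W + (1 + 1/m)·B, with Barnard–Rubin small-sample degrees of
freedom). Individual cost components are imputed separately and totals
recomputed from components — never imputed directly — to retain
information from partially observed residents. The predictor set is
arm, age, sex, baseline utility, baseline COOP WONCA and baseline ADL
restriction (GARS); the chained-equation engine is statsmodels' MICE,
with this module owning predictor specification, seeding, validation
and diagnostics.

Numerical choices: k = 3 donors per predictive-mean match and matching
on the raw cost scale. Both were selected by benchmarking parameter
recovery on generator data with retained truth; log-scale matching and
larger donor pools measurably increased the small finite-sample
matching bias that PMM exhibits when missingness concentrates in one
region of the predictor space. That residual matching bias (well under
1% of a component mean here) is an intrinsic property of
nearest-neighbour donor selection, not of the engine — a hand-rolled
type-1 PMM reproduces it on a correctly specified linear benchmark.
PMM guarantees every imputed value lies within the observed donor
range, which suits heavily right-skewed costs.

Degenerate inputs: a dataset with no missing targets returns m
identical copies with a warning; a target that is 100% missing is a
hard error; missing values reaching the bootstrap stage are a hard
error (imputation must precede).

## Bootstrap and intervals

Arm differences and cost-effect pairs use within-arm nonparametric
resampling (B = 5000 by default; B ≥ 100 enforced for intervals). For
cost-effectiveness, (ΔC, ΔE) is computed on the *same* resample so the
cost-effect correlation is preserved. Across imputed datasets the
package bootstraps within each completed dataset and stacks the m·B
replicates (the per-imputation results are also written); bootstrap-
then-pool versus pool-then-bootstrap is not settled practice, and
stacking is the documented convention here.

Intervals: percentile (order statistics, ties broken by linear
interpolation); BCa (median-bias correction z0 from the replicate
distribution, acceleration a from the jackknife skewness of the pooled
leave-one-out statistics — with z0 = a = 0 the endpoints reduce exactly
to percentile); and an analytic ABC variant for the mean difference
computed from empirical influence values without resampling (for a
linear statistic the quadratic ABC terms vanish and z0 = a). A constant
arm makes the interval collapse to a point and is flagged; BCa falls
back to percentile there because z0 is undefined.

## Decision analysis

Effect direction is an explicit per-outcome attribute; all ratios,
quadrants and curves work on benefit-signed effects, which removes the
sign ambiguity of "negative ICERs" (a negative ratio can mean dominant
or dominated, so such ratios are reported but flagged uninterpretable).
Quadrant shares classify replicates by sign with boundary ties counted
to the south/west, so shares always sum to one. The CEAC uses a strict
net-monetary-benefit inequality (λ·ΔE − ΔC > 0; ties are not
cost-effective — conservative and measure-zero for continuous data).
Default λ grids: €0–10,000 in €1 steps for the point-scale outcomes,
€0–500,000 in €1,000 steps for QALYs — the ranges on which such
outcomes are conventionally discussed. ICERs are rendered to whole
euros in reports.

## The synthetic trial generator

The generator emulates the *statistical structure* the analysis
assumes, not the care processes:

* two arms of 5 homes, resident counts Poisson around 46, ~74%
  participation (so ≈ 460 invited, ≈ 340 randomized);
* baseline SF-6D utilities truncated-normal 0.64 ± 0.10; follow-up
  utilities add a configurable arm effect (default −0.0065, matching a
  −0.0016 QALY difference), a home intercept and noise;
* COOP WONCA: six ordinal dimensions from a discretized normal with
  total ≈ 18 ± 3.9; follow-up change ≈ 0.65 in the control arm plus a
  +0.2 arm effect. Rounding and clipping to the 1–5 chart range
  attenuate the planted change effect somewhat; direction is preserved
  but the realized effect is smaller than configured, which is accepted
  (the study itself found no significant difference on this outcome);
* a 32-indicator quality panel: heterogeneous prevalences averaging
  17.63%, Bernoulli applicability (80%), and an intervention-arm
  log-odds shift solved numerically so the *expected* arm difference in
  the sum score equals the configured effect (default −6.51 points)
  exactly;
* per-group gamma costs (lognormal selectable) with control-arm means
  (389, 533, 429, 282) and shapes (0.36, 0.14, 0.60, 0.34) matching the
  reported means and standard errors; the configured total cost effect
  (€197) is distributed over groups in the proportions of the reported
  group differences. A mean-one lognormal loading ties informal-care
  and medication costs to baseline ADL restriction so that selective
  dropout genuinely biases complete-case cost means — otherwise
  imputation checks would be vacuous. Group costs are split into
  resource-use records by fixed shares with quantities = cost / unit
  price (continuous; interpret as rates);
* ~10% mortality, ~1.5% missing-baseline, and logistic
  missing-at-random dropout on age and GARS. The default coefficients
  (−0.8452, 0.0433/year, −0.0443/point) were calibrated once,
  deterministically, so that ~31% of surviving residents drop out,
  non-completers average ~2 years older and ~3.4 GARS points less
  restricted than completers. Interview-sourced data (follow-up
  utility, COOP WONCA charts, the indicator panel, informal-care hours)
  vanish with dropout; record-based cost groups are additionally
  missing completely at random (10% per component) to create
  component-level patterns; deaths mask all follow-up data.

Everything pre-missingness is retained in `*_true` columns so
imputation bias is measurable against generator truth. Identical
(config, seed) reproduces the dataset bit for bit; all pipeline
randomness descends from a single root seed split per stage.

What the generator does **not** emulate: the content of the underlying
assessment instrument, risk adjustment of the indicators, longitudinal
trajectories beyond two time points, the published trial's 201/139 arm
imbalance (arms are balanced by design here), or informative death.
Passing tests therefore show that the *estimators* behave correctly
under the stated data-generating assumptions — not that those
assumptions hold in any particular real dataset.

## Validation problem sizes

The test suite checks moment calibration on a ~10,000-resident
no-cluster configuration (3 Monte-Carlo SEs), bootstrap interval
coverage of a planted €405 gamma-cost difference over 500 simulations
at n = 150/arm with B = 2000 (band 92–98%), and multiple-imputation
recovery of the MAR-masked informal-care mean over 200 simulated
~1,000-resident trials (|bias| < 3 Monte-Carlo SEs). Pipeline
determinism is asserted byte-for-byte on the report tables.

## Known limitations

* With five homes per arm, between-home variation dominates arm-level
  summaries; single-seed pipeline outputs move substantially between
  seeds. This is a property of the design being emulated, not a defect.
* PMM's residual finite-sample matching bias under strong covariate
  shift (see above).
* The COOP WONCA change effect is attenuated by ordinal
  rounding/clipping.
* No discounting (6-month horizon) and no productivity costs.
* Fieller-type ICER intervals and net-benefit regression are out of
  scope; the CEAC supersedes them here.
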