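# Methods

This note records the model's assumptions, the parameters that matter, the
numerical choices made where the design was genuinely open, and the limits
of what the bundled fixture set can show.

## Model structure

The simulation is a continuous-time discrete-event model over a fixed pool
of simulants. Each person is fully described by (a) fixed attributes — sex,
entry age (uniform on 55–80 in the fixture), smoking category — and (b) a
set of latent draws made once per seed: the disease course, the other-cause
death time, participation uniforms, per-screen test uniforms, and a single
survival quantile. Because these draws are keyed on (seed, person id,
stream), every strategy arm replays the identical person; differences
between arms are produced only by the intervention (common random numbers).

### Natural history

Age at preclinical onset is `LogNormal(μ, σ)` on age (not time-from-entry);
draws above the lifetime horizon (age 100) mean no lifetime onset. Onset is
sampled unconditionally, so occult prevalence at entry and subsequent
incidence are internally consistent; a course whose clinical presentation
precedes entry describes someone who could not have enrolled undiagnosed and
is redrawn whole.

From onset the tumour walks the ladder IA→IB→IIA→IIB→IIIA→IIIB→IV without
skipping. In each occupied stage two independent exponential clocks compete:
progression (rate `λ_s`, absent in stage IV) and clinical presentation (rate
`ρ_s`). The independent-competing-exponentials construction is stated
explicitly because it fixes the calibration likelihood: it implies stage
sojourns `Exp(λ_s + ρ_s)` and `P(present in s) = ρ_s/(λ_s + ρ_s)`, both of
which the tests check against closed forms. Death from occult (undiagnosed)
disease is impossible, so the course never interacts with other-cause
mortality until diagnosis.

In the base case all simulants share one rate set. The heterogeneity
scenario multiplies each person's progression and presentation rates by a
unit-mean gamma frailty (variance 0.25 in the shipped scenario).

### Other-cause mortality

A per-age, per-sex life table supplies all-cause rates; the adjusted
other-cause hazard is `all_cause × smoking_factor − lung_cancer_rate`,
floored at zero with a warning (a transcription error must not produce an
invalid distribution). The table closes at age 100 with certain death.
Sampling is exact inverse-CDF on the piecewise-linear cumulative hazard.

### Risk score and eligibility

The published risk questionnaire is represented by its modelled information
content only: predicted risk (%) is lognormal noise around a baseline median
(2%), multiplied by 3 when occult disease is present at entry or onset
occurs within 3 years. Thresholding this proxy at ≥3/4/5% therefore enriches
the invited population in true short-term risk, which is all the downstream
model uses. A genuine external risk equation can be plugged in by setting
`risk_percent` on profiles before strategy evaluation. Age-window bounds are
inclusive on completed years; risk/eligibility is checked at entry only.

### Screening pathway

Designs: S = one screen at entry; T = screens at 0, 1, 2 years (not age
capped, per protocol); A/B = annual/biennial screens while attained age is
strictly below 80. "Shortly following entry" is read as offset 0. Joiners
attend every scheduled screen they survive to (full concordance). The LDCT
test is a binary gate — sensitivity for any occult disease, specificity for
the disease-free — independent of stage and tumour characteristics. A true
positive diagnoses immediately at the occupied stage; false negatives stay
in the programme; false-positive and indeterminate results are one category
with a workup cost and a temporary disutility, never a diagnosis. A cancer
presenting clinically between two scheduled screens of a joined programme is
an interval cancer; before the first or after the last screen it is an
ordinary clinical presentation.

### Survival link and bias control

Post-diagnosis survival depends only on stage at diagnosis (exponential per
stage in the fixture; the family is a named parameter so a transcribed set
can choose another). One uniform quantile per person is pushed through the
stage-specific inverse CDF in both arms. Consequences, all pathwise:

* same-stage earlier detection ⇒ identical lung-cancer death date in both
  arms (no survival benefit from lead time alone);
* earlier-stage detection ⇒ survival drawn from the earlier stage's
  distribution, clamped to be no earlier than the control candidate
  (screening can never hasten lung-cancer death);
* control never diagnosed before other-cause death ⇒ over-diagnosis: the
  screening arm gains a diagnosis (and its costs) but no lung-cancer death
  is allowed in either arm.

The clamp is applied to death *times* per individual, not to cohort-level
risks; the population corollary (lung-cancer deaths under screening ≤ under
no screening) is asserted in tests. Five-year survival is computed from the
date of diagnosis, so screen detection inflates it even with zero mortality
benefit — the deliberate lead-time/length-bias artefact of this outcome,
reported as such.

### Economics

Utility flows are integrated continuously with discount factor `(1+r)^{-t}`
(closed form per constant segment; r = 0.035/year default). The utility path
is the sex/age-band baseline until diagnosis, then broad-stage utility
(stage I keeps baseline, including band steps) constant until death. Screen
attendance (0.01 for 2 weeks) and false positives (0.063 for 3 months) are
rectangular decrements truncated at death. Point costs are discounted at
their event time. Care costs are a constant flow for ≤2 years post-diagnosis
(year 2 scaled by a factor), truncated at death; a false-negative screen
accrues nothing until true diagnosis; end-of-life cost attaches to
lung-cancer deaths only. Admin costs: invite to every invitee, questionnaire
scoring to responders, follow-up invite to joiners (the split for
non-responders is not externally specified; invite-to-all is the package's
choice). The four reporting categories are screening administration, LDCT
screening, lung cancer care (which includes false-positive workup) and
end-of-life.

### Strategy engine

Per-person primary outcomes use the invited-population denominator
(including non-participating invitees); participant-denominator metrics
mirror trial-style tables. Frontier construction is the greedy minimum-ICER
walk from the comparator on per-invitee incrementals, which implements both
strict and extended dominance; ICERs are computed on unrounded means.
Zero-cell 2×2 tables for the early-diagnosis odds ratio use the
Haldane–Anscombe 0.5 correction. Monte Carlo standard errors of the paired
incrementals are reported with every aggregate. NMB optimisation is an
exhaustive grid search with ties broken toward narrower age windows; no
screening (NMB 0) is always a candidate.

## Calibration

The simulated likelihood runs a vectorised cohort (entry ages 55–74, three
screening rounds at 0/1/2 years) through the same onset + competing-clocks
model via inverse-CDF transforms of a fixed uniform block, so the
log-posterior is a deterministic function of the parameters (common random
numbers across proposals) and chains are bit-reproducible. Summaries:
detection proportion per round, early-stage share of detections, clinical
presentations within 3 years. Likelihood families are binomial or Poisson
per target. The sampler is random-walk Metropolis on log-parameters with the
log-scale Jacobian, burn-in fraction 0.5 by default. Calibrated-set
membership is configurable (sensitivity, onset median/sigma, progression and
presentation scale multipliers). The simulator intentionally omits
other-cause death within the short trial window and treats
pre-enrolment presenters as not enrolled; these simplifications are
acceptable for the 3-year trial horizon the summaries cover but mean the
calibration cohort is not the cost-effectiveness pool.

A practical note on synthetic-target experiments: the inner cohort's Monte
Carlo resolution acts as extra likelihood noise, so target denominators
should not be much larger than the inner cohort size, otherwise the
posterior concentrates on simulator noise rather than the generating values.

## Uncertainty

Univariate analysis perturbs each scalar parameter ±δ with the pool seed
fixed and records the ICER both ways (invalid perturbations are flagged, not
dropped). The scenario registry ships `fp_disutility_zero`, `discount_zero`
and `heterogeneity_on`; overrides are dotted parameter paths and unknown
paths are configuration errors. PSA samples parameter vectors (beta for
probabilities/utilities, gamma for costs/rates by default), re-runs the grid
on a reduced inner pool (default 5,000; Monte Carlo error scales as
1/√n and is visible in the reported standard errors), and tabulates the
per-threshold NMB winner into a CEAC.

## Fixture parameters and what the tests do (and do not) show

Published point values appear exactly in the fixture: sensitivity 0.709,
specificity 0.624, response 0.307, joining 0.465, LDCT £98.80, the 75–84
utilities 0.7816/0.7531, stage utilities 0.77/0.77/0.76, the two
disutilities and durations, discount 3.5%, pool 20,000. The remaining inputs
are placeholders chosen once for plausible epidemiology, not calibrated
values: onset `LogNormal(ln 105, 0.25)` (≈3–4% occult onset by the
mid-60s, ≈40% lifetime onset before the competing clocks act), progression
rates 1.0–1.4/year, presentation rates rising 0.03→1.2/year across stages,
exponential stage survival with medians 8→0.6 years, Gompertz-style life
table, stage care costs £9,000–13,000 in year 1 with a 0.30 year-2 factor.

Because of this, quantities driven mainly by the published uptake and test
parameters (screens per participant, false positives per participant)
reproduce trial-scale magnitudes, while quantities driven by the natural
history and costs (ICERs, mortality reduction, per-100,000 counts) are
internally consistent but not externally calibrated. Passing tests
demonstrate the mechanics — competing-risks arithmetic, the pathwise clamp,
discounting accuracy, frontier coherence, calibration recovery,
determinism — not agreement with any published cost-effectiveness table;
that requires loading a transcribed calibrated parameter set through
`load_parameter_set`.

## Problem sizes used in the shipped runs

The acceptance script uses the full 20,000-simulant pool across all 48
strategies. The test suite uses 3,000-simulant pools for population-level
properties, 20,000 for the full-pool pathwise-clamp checks, n = 100,000 for
closed-form rate checks, and a reduced calibration experiment (inner cohort
8,000, 4,000 iterations) for parameter recovery — sizes chosen as the
smallest that make the assertions statistically meaningful.

## Known limitations

No smoking-behaviour change, incidental findings or radiation-induced
cancers; no histology, tumour location or nodule-size growth; no
nodule-management algorithm (the test is a pure binary gate); no
post-diagnosis progression modelling (outcomes are stage-at-diagnosis
averages); no societal perspective; currency/price-year are metadata only
(no inflation arithmetic). Eligibility is not re-checked at repeat screens.
The pool is shared across strategies by construction; resampling per
strategy would only add Monte Carlo noise to contrasts.
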