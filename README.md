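# lungscreen

An individual-patient discrete-event simulation of low-dose CT (LDCT) lung
cancer screening programmes in a UK-style setting, built around an explicit
model of the disease's **natural history**: each simulant carries a latent
tumour timeline — lognormal age at preclinical onset, then competing
exponential clocks for stage-by-stage progression (IA → IB → … → IV) and for
stage-specific clinical presentation — and screening interacts with that
timeline through a binary sensitivity/specificity test gate.

The package is for health-economic modellers and screening researchers who
want a scriptable, tested alternative to spreadsheet implementations: it
evaluates 48 screening strategies (4 programme designs × 4 entry-age windows
× 3 risk thresholds) against no screening on discounted lifetime costs
(NHS/PSS perspective) and QALYs, with Bayesian MCMC calibration of the
natural history and full uncertainty analysis.

## The model in brief

* **Population.** A shared pool of 20,000 simulants (ages 55–80, current or
  former smokers) with smoking-adjusted life-table mortality. Every source of
  per-person randomness is a named substream keyed on (seed, person id), so
  strategy arms are common-random-number (CRN) paired.
* **Natural history.** Onset age `A ~ LogNormal(μ, σ)`; in stage *s* the
  sojourn is `Exp(λ_s + ρ_s)` split between progression (rate `λ_s`) and
  clinical presentation (rate `ρ_s`) by the competing-exponentials rule
  `P(present in s) = ρ_s / (λ_s + ρ_s)`. Stage IV has no onward progression.
* **Screening.** Designs S (single screen), T (triple: 0, 12, 24 months),
  A (annual) and B (biennial; A/B capped strictly before the 80th birthday).
  Eligibility = age window + predicted-risk threshold (a questionnaire
  proxy); participation ~ Bernoulli(0.307) × Bernoulli(0.465). The LDCT test
  has sensitivity 0.709 and specificity 0.624; false positives and
  indeterminates are equivalent (workup cost + temporary disutility).
* **Survival link (bias control).** Post-diagnosis survival depends only on
  stage at diagnosis, drawn by inverse CDF from a *single common quantile*
  per person across stages and arms. Same-stage earlier detection therefore
  confers zero survival benefit (lead-time bias mitigation); earlier-stage
  detection extends survival but is clamped so screening can never hasten a
  lung-cancer death; screen-detected cases whose counterfactual never
  presents are counted as over-diagnosis.
* **Economics.** Continuous discounting at 3.5%/year; age-banded baseline
  utilities (e.g. 0.7816 male / 0.7531 female at 75–84), stage utilities
  II/III 0.77, IV 0.76, stage I at baseline; LDCT scan £98.80; care costs for
  ≤ 2 years post-diagnosis; end-of-life cost at lung-cancer deaths.
* **Outputs.** Per-strategy incremental cost/QALY (invited-population and
  participant denominators), ICERs, the dominance-pruned cost-effectiveness
  frontier, net-monetary-benefit optimisation, and secondary outcomes
  (screens and false positives per participant, lead time, odds ratio of
  early-stage diagnosis, diagnoses and lung-cancer deaths per 100,000,
  5-year survival, mortality reduction).

The bundled fixture parameter set is complete and runnable with no external
data; the natural-history rates, stage survival, care costs and life table
in it are documented placeholders (see `docs/methods.md`), with published
point values (test characteristics, participation, utilities, LDCT cost)
appearing exactly.

## Worked example

```python
import lungscreen as ls
from lungscreen.screening import StrategySpec

params = ls.default_parameter_fixture()
pool = ls.build_pool(params, seed=1, n=20_000)     # shared CRN pool
res = ls.run_strategy(pool, StrategySpec("S", 60, 75, 3.0))

print(res.n_invited, res.n_participants)           # 3418 469
print(round(res.inc_cost_invited, 2))              # 48.12  (£ per invitee)
print(round(res.inc_qaly_invited, 5))              # 0.0041 (QALYs per invitee)
print(round(res.icer_vs_none))                     # 11749  (£ per QALY)
print(res.screens_per_participant)                 # 1.0
print(round(res.fp_per_participant, 3))            # 0.377
```

Of 20,000 pool members, 3,418 are invited (age 60–75 and predicted risk
≥ 3%) and 469 join. Each joiner attends exactly one screen (design S) and
0.377 of them receive a false-positive/indeterminate result (≈ specificity
shortfall, 1 − 0.624). Versus the same people unscreened, the programme
costs £48.12 and gains 0.0041 QALYs per invitee — an ICER of £11,749 per
QALY *under the placeholder fixture parameters* (calibrated inputs change
these numbers; that is the point of the calibration module).

The same grid run from a shell:

```bash
lungscreen grid --seed 1                 # all 48 strategies + comparator -> grid.csv
lungscreen frontier --seed 1             # dominance-pruned frontier -> frontier.csv
lungscreen optimise --design S --wtp 20000
```

## Calibration and uncertainty

`lungscreen.calibration` fits natural-history parameters and test
sensitivity to trial-style summary counts (binomial/Poisson likelihood) by
random-walk Metropolis on log-parameters, with the simulated likelihood held
on common random numbers so the posterior surface is deterministic and runs
are bit-reproducible. Observed trial counts are not bundled; synthetic
targets and a CSV schema (`name,count,denominator,family`) are provided.
`lungscreen.uncertainty` supplies tornado-style univariate sensitivity
analysis, a scenario registry (`fp_disutility_zero`, `discount_zero`,
`heterogeneity_on`), and probabilistic sensitivity analysis with
cost-effectiveness acceptability curves.

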