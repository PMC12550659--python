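# Methods

## The cascade model

`treatcascade` models sequential treatment of a closed cohort of depressed
patients. Response (≥50% symptom reduction) to each treatment step is a
Bernoulli event; patients who do not respond to step k are all offered step
k+1. With per-step response probabilities p₁, p₂, … the fraction of the
cohort still unresponsive after k steps is the survival product

    S_k = ∏_{j≤k} (1 − p_j),    S_0 = 1.

The cascade stops at the first step K after which fewer than
`cohort_size × (1 − coverage_target)` patients remain unresponsive — with
the default cohort of 100 and coverage target 0.99, "fewer than one patient
left". The quantity of interest is the total number of treatments delivered
across all steps, and in particular the *excess* treatments (total minus
cohort size), since every patient needs at least one treatment anyway.
Innovations are compared by the percentage reduction in excess treatments
they achieve relative to a baseline scenario.

The process is an absorbing Markov chain: transient states are "awaiting
treatment k", each absorbing into "responded" with probability p_k and
otherwise advancing to k+1. `markov_expected_treatments` computes the
expected treatments per patient as the first-row sum of the fundamental
matrix N = (I − Q)⁻¹, which equals Σ_{k=0}^{K−1} S_k. The matrix route is
deliberately redundant: it cross-checks the step-by-step ledger through an
independent computation, and the equality is asserted to 1e−10 in the test
suite on randomized schedules.

## Schedules

Three generated schedule kinds:

- **constant** — p_k = p₁ at every step. Default reference value p₁ = 0.42,
  a meta-analytic response rate to psychological treatment.
- **geometric_decline** — p_k = p₁(1 − d)^{k−1}: each treatment is a fixed
  fraction d less effective than the previous one. The headline scenario
  uses p₁ = 0.50 (first-ever treatment responds better) and d = 0.10.
- **linear_decline** — p_k = max(p₁ − (k−1)·d, floor). The floor defaults
  to 0.01 so probabilities stay positive and the cascade terminates; it is
  configurable. This kind exists for sensitivity analyses on the shape of
  the decline, which is not empirically known.

Schedules are capped at `max_steps` (default 100) as a guard against
non-terminating cascades when probabilities are tiny.

## Effect sizes and innovations

An innovation's strength can be given as a standardised mean difference
(SMD) increment over the comparator. SMDs are translated to response-rate
changes with the Hasselblad–Hedges log-odds transform,

    ln(OR) = SMD × π/√3,   logit(p_new) = logit(p_base) + ΔSMD × π/√3,

the standard conversion between standardised mean differences and odds
ratios under a logistic outcome distribution. A ΔSMD of 0.15 over a 50%
baseline gives 0.5676. The converted rate is rounded half up to the nearest
whole percent (0.57) before cascade use: meta-analytic effect sizes carry no
more precision, and cascade scenarios are specified at whole-percent
schedules throughout. (The probit conversion, ΔSMD → Φ-scale, would give
56% here; the log-odds transform is the one consistent with the rest of the
model's arithmetic.)

Scope of an innovation:

- **first_step_only** — a better first-line treatment; later steps keep
  their original (declined) rates.
- **all_steps** — e.g. better patient–treatment matching or progress
  feedback; the schedule is regenerated from the boosted first-step rate
  with the original decline, so under geometric decline every step gains by
  the same multiplicative factor.
- **single_step** — a treatment for a specific stage, e.g. restoring step 3
  (treatment-resistant patients, baseline rate 0.405) to first-treatment
  effectiveness (0.50); one entry is replaced outright.

"Doubling" an innovation is modelled on the percentage-point scale of the
rounded converted rate: the +7-point gain (50% → 57%) doubles to +14 points
(→ 64%). Doubling on the log-odds scale instead would give 63%; the
point-scale convention matches how the scenario totals are quoted and is
the package's fixed choice.

## Rounding convention

The benchmark scenario totals are head-counts of a 100-patient cohort, so
treated counts are reported as whole patients. The convention used here,
chosen once and exposed alongside an exact alternative:

- Survival S_k always propagates **continuously**; rounding never feeds
  back into the state. (Propagating rounded integer cohorts stalls near the
  stopping threshold: rounded responder counts reach zero while one or two
  survivors remain.)
- Under the default `per_step_half_up` mode the treated count at step k is
  `round_half_up(cohort_size × S_{k−1})`, and the total is the sum of these
  integers. Under `continuous` the real-valued counts are summed; for a
  constant schedule this equals the geometric-series closed form
  `cohort × (1 − (1−p)^K)/p`.
- Reported percentages are rounded half up to whole percent. Half-up (not
  banker's) rounding is used everywhere a count or percentage is reported.

The two modes differ by at most K/2 patients over a K-step cascade (each
step contributes at most 0.5 of rounding error); the suite asserts this.

## Known discrepancies

Three figures sometimes quoted alongside these scenarios are not reproduced
by the model under any rounding convention tried, and the package reports
its own values rather than tuning to them:

- Mean treatments per patient in the declining baseline: the model gives
  230/100 = 2.3, not 2.7.
- Cohort unresponsive after two steps in the declining baseline: the ledger
  gives 27.5% (half-up: 28%), sometimes quoted as 27%.
- "Doubling the first treatment only": no conversion considered (log-odds
  doubling → p₁ = 0.63, excess 70; point doubling → p₁ = 0.64, excess 93)
  yields the quoted excess of 85, which would need p₁ ≈ 0.66. The scenario
  is therefore not encoded in the bundled suite.

These are asserted as-is in the test suite so that any change to the model
that silently "fixes" them is caught.

## Monte Carlo cohort simulation

`simulate_cohort` draws patient-level trajectories: patient i undergoes
independent Bernoulli trials with probabilities p₁, p₂, … until first
success or a censoring cap. Implementation notes:

- One `numpy` PCG64 stream seeded by the caller; patient i consumes a fixed
  slice of the stream (`cap` uniforms), so a patient's trajectory is
  invariant to the number of patients simulated after them, and identical
  inputs give byte-identical exported tables.
- The cap records censoring, not failure-to-ever-respond; at the default
  scenarios' caps (the deterministic cascade's own step count) under 1% of
  patients are censored, matching the >99% coverage framing.
- The simulator emulates exactly what the deterministic model assumes:
  homogeneous per-step probabilities, independence across patients and
  steps, no relapse, no dropout. Passing stochastic tests therefore
  validates the cascade arithmetic, not the model's realism on clinical
  data — between-patient heterogeneity (frailty), relapse and selective
  dropout are all absent by design and are extension points, not options.

`estimate_schedule_from_trajectories` recovers p_k as responders-at-k over
patients reaching step k, with 95% binomial intervals — normal
approximation, switching to exact Clopper–Pearson when a step's responder
or non-responder count falls below 5. Default Monte Carlo sizes in the
tests and analysis scripts are 100 000 patients with fixed seeds, which
puts standard errors near 0.007 treatments — small enough to detect any
real defect in the cascade arithmetic while the full suite runs in seconds.

## Sensitivity options

Coverage targets of 0.70 and 0.80 (clinically meaningful alternatives to
>99%) shorten the cascade and are supported directly through
`CascadeConfig`; linear decline substitutes for geometric via the schedule
kind. Non-convergence within `max_steps` raises by default and is instead
flagged on the result when `allow_nonconverged` is set, which the suite
runner's permissive mode uses for low-probability sweeps.

## Limitations

The model is deliberately mechanistic: response is the only outcome, all
treatments in a step are interchangeable and equally burdensome, the
decline schedule is an assumption rather than an estimate, and there is no
relapse, dropout, or patient heterogeneity. The benchmark is a yardstick
for comparing innovations' potential, not a forecast of clinical practice.
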