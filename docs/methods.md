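# Methods

## The task

The Iowa Gambling Task (IGT) presents four decks of cards. Every draw
pays a fixed gain; some draws also incur a loss, delivered on fixed
positions within a repeating 10-draw cycle. Decks A and B pay 100 per
draw but lose 250 net per cycle; decks C and D pay 50 per draw and gain
250 net per cycle. B and D concentrate their penalty on a single
position (they "win" on 90% of draws); A and C spread five penalties
over the cycle (50% win rate). The package ships these canonical
magnitudes as the default schedule (`orligt/data/classic_schedule.yaml`);
all magnitudes are configurable, and a shuffled-within-cycle dialect
(`shuffle_within_cycle`) randomizes the loss positions while preserving
every per-cycle aggregate, since published task variants differ on this
point.

## The ORL model

Choice behaviour is modelled with the Outcome-Representation Learning
(ORL) model. Three latent 4-vectors evolve across trials:

* **EV** — expected value, updated for the chosen deck j by a delta rule
  `EV_j += A * (x - EV_j)`, with learning rate `A = A_rew` when the net
  outcome `x >= 0` and `A = A_pun` otherwise. The published equation
  typography drops the parentheses of the delta rule; the literal reading
  would make the learning rate a no-op, so the standard delta form is
  used.
* **EF** — expected win frequency. The chosen deck moves toward
  `sgn(x)` with the same rate `A`. Unchosen decks receive a fictive
  ("reversal learning") update toward `-sgn(x)/3` — the opposite
  direction, split over the three unchosen decks — using the *opposite*
  learning rate (`A_pun` on gain trials, `A_rew` on loss trials). The
  original model description does not print this update; the form here
  follows the reference implementation of the model family (hBayesDM's
  ORL). **This is the one equation adopted from outside the printed
  description**, and the tests' independent oracle encodes the same
  choice, so agreement there validates internal consistency, not the
  historical fidelity of this term.
* **PS** — perseveration strength. After each choice the chosen deck's
  PS is set to `1/(1+K)` and all other decks' PS are divided by `(1+K)`,
  with `K = 3**K' - 1`.

Deck values `V_j = EV_j + beta_F * EF_j + beta_P * PS_j` enter a softmax
with sensitivity fixed at 1. Five free parameters: `A_rew`, `A_pun` in
[0, 1]; `K' >= 0` (bounded above by 5 in estimation, since `3**K'`
otherwise overflows and the likelihood is flat there anyway); `beta_F`,
`beta_P` unbounded.

Conventions (configurable, defaults chosen to match the reference
implementation): a single net outcome `x = gain - loss` per trial; `x`
divided by 100 before entering the equations so EV is commensurate with
EF in [-1, 1]; `x = 0` routed to the reward branch with `sgn(0) = 0`;
all latent vectors initialized at zero, making the first choice uniform
(log-likelihood exactly `-ln 4`).

Useful consequences used as test anchors: with all five parameters zero
the likelihood of any 100-trial sequence is exactly `-100 ln 4`; from
zero initialization EF stays in [-1, 1] and PS in [0, 1] for any
admissible parameters.

## Synthetic studies

`synthetic_study` generates complete 2x2 (alcohol x mood) studies: 40
subjects per cell by default, 100 trials each on the classic schedule.
Reward-learning-rate cell means are `0.167 + 0.13*alcohol + 0.12*mood`
(no interaction); punishment-rate cell means are flat at `0.091`. These
anchors are the observed baseline-cell means and condition effects of
the study the generator emulates. Effects are injected on the raw rate
scale because the downstream group models are linear in the raw
estimates.

Bounded parameters are drawn from truncated normals whose *location* is
solved numerically so that the realized (post-truncation) mean equals
the documented cell mean — naive truncation at 0 would inflate a mean of
0.167 (SD 0.18) to about 0.23. Population values for the remaining
parameters are package choices, unconstrained by any published number:
`K' ~ 0.3 (0.5)`, `beta_F ~ 1.5 (0.5)`, `beta_P ~ 1.0 (0.5)`. They were
chosen once to produce a realistic frequency-seeking choice pattern
(decks B and D preferred, A avoided) and are documented, configurable
constants.

Mood, stress and intoxication ratings exist to exercise the
manipulation-check and responder-filter code: change scores are drawn
from normals matching the emulated study's manipulation checks (mood
change -3.19 (1.76) under negative induction, -0.01 (1.32) under
neutral; stress +4.05 (2.26) vs +0.35 (1.62); intoxication 4.96 (1.85)
vs 1.06 (0.33)), added to a pre-rating and clipped to the 1-10 scale.
They are statistically independent of choice behaviour by default.

What the generator does **not** emulate: real IGT data contain choice
stochasticity not captured by any parametric policy, missing trials,
attention lapses, and correlations between affective state and play.
Passing tests therefore demonstrate that the pipeline recovers what it
injects under the model's own assumptions — the standard parameter- and
effect-recovery validation for cognitive models — not that the model is
true of human data.

## Hierarchical estimation

`fit_hierarchical` samples a non-centered hierarchy: each subject's
unconstrained parameter vector is Normal(group mean, group SD)
per-parameter, with Normal(0, 1) priors on group means and
half-Normal(0, 1) priors on group SDs. Unconstrained scale: logit for
the learning rates, scaled logit for `K'` on (0, 5), identity for the
betas. All 160 subjects are pooled into one hierarchy (a per-subset fit
is possible by passing any subject subset).

The sampler is an adaptive Metropolis-within-Gibbs scheme built on a
vectorized (numba-compiled) likelihood that scores all subjects in one
call (~0.6 ms for 160 subjects x 100 trials). Each iteration:

1. per-parameter random-walk proposals for every subject at once,
   accepted independently per subject (valid because subject likelihoods
   are independent given group parameters); step sizes adapt toward 44%
   acceptance during warmup;
2. two prior-preserving autoregressive (pCN) refreshes per parameter,
   which resample subject values partly from the group prior — this is
   what keeps the *spread* of subject values, and hence the group SDs,
   mixing under strong shrinkage;
3. conjugate Gibbs updates of the group means;
4. log-scale random-walk updates of the group SDs;
5. joint translation and scale moves that shift or rescale a group mean
   or SD together with every subject's value — the moves that traverse
   the hierarchy's slow directions.

Presets: `full` = 4 chains, 1000 warmup + 1000 draws, thin 2 (the
default); `test` = 2 chains, 350 + 350, used where a reduced budget is
appropriate (about 40 s for 160 subjects on one core). Convergence is
summarized by split-Rhat and ESS on the group-level parameters via
arviz; Rhat > 1.05 is recorded as a warning in the diagnostics, never
raised.

**Known limitation**: in large studies (160 subjects) the group-SD
posteriors of the weakly identified parameters (`K'`, `beta_P`) mix
slowly — a funnel-like geometry in which the subject-value spread
re-equilibrates slowly — and their Rhat can remain around 1.1-1.4 even
at the full budget. Subject-level posterior means and group means are
stable across presets and chains (recovery correlations agree to two
decimals between the test and full presets), so downstream two-stage
analyses are unaffected; the warning is surfaced honestly in
`FitResult.diagnostics`.

`fit_subject_map` provides a fast per-subject MAP alternative
(multi-start L-BFGS on the unconstrained scale with independent normal
priors), used for quick looks and degenerate-input behaviour; the
hierarchical posterior mean is the estimator consumed by the group
analyses.

Parameter recovery on the default study (hierarchical posterior means
vs generating values, 160 subjects): correlations around 0.8 for both
learning rates, around 0.65 for `beta_F`, 0.55-0.6 for `beta_P`, and
0.3-0.35 for `K'` — the expected ordering, since 100 trials carry
little information about memory decay.

## Model comparison

The baseline model chooses uniformly, so its pointwise log-likelihood is
`ln(1/4)` per trial and its LOOIC is exactly `2 T ln 4` per subject.
The ORL model's LOOIC uses PSIS-LOO (arviz) over posterior draws of the
per-trial log-likelihoods, treating trials as the resampling unit within
subject, conditional on the subject's parameters — the only construction
consistent with counting per-subject fits. When more than 10% of
Pareto-k diagnostics exceed 0.7 the estimate falls back to WAIC with a
warning. On ORL-generated data the ORL fit beats the baseline for
essentially all subjects (typical per-subject delta-LOOIC around 50);
on uniform-random choices the advantage disappears (median delta near
0, roughly half the subjects on either side).

## Behavioral scoring and the responder filter

The primary behavioral outcome is the count of C/D choices in trials
41-100 (0-60). Block summaries use 5 blocks of 20 trials
(configurable). Cohen's d uses the pooled-SD denominator. The
mood-responder filter implements the preregistration wording literally:
negative-mood subjects are kept iff their mood change is <= -3 (a
decrease of exactly 3 counts as responding); neutral-mood subjects are
kept iff the absolute change is <= 2; missing ratings exclude with
reason "missing". The filter is idempotent.

## Group-level inference

Three Bayesian linear models regress, in turn, the winning-deck score,
the reward-rate estimates, and the punishment-rate estimates on
dummy-coded alcohol, mood, and their product. The learning-rate models
are two-stage: subjects' posterior means enter as outcomes. A
full-uncertainty mode (propagating subject-level posteriors) was
considered and rejected as the default because the emulated analysis is
itself two-stage.

Priors, "weakly_informative" preset: Normal(0, 2.5 SD(y)) on effects,
Student-t(3, median(y), 2.5 MAD(y)) on the intercept, half-Student-t(3,
0, 2.5 SD(y)) on the residual scale. The "flat" preset drops the effect
priors (improper flat), mirroring regression-software defaults, for the
prior sensitivity analysis. Sampling uses a small adaptive random-walk
Metropolis kernel on (coefficients, log sigma) — the posterior is
5-dimensional and near-Gaussian, where this kernel is adequate and
exactly seedable; chains start from jittered least-squares solutions.

Inference rules: the behavioral model is judged against a ROPE of +/-3
winning draws ("effect" if the 95% equal-tailed CI is entirely outside,
"practically null" if entirely inside, else "inconclusive"); the
learning-rate models use the CI-excludes-0 rule. Equal-tailed intervals
(not HDIs) match the reporting convention of the emulated analysis.

Sensitivity analyses: (a) rerun after the responder filter (ORL
estimates are reused; only the group models are refit, consistent with
the two-stage design); (b) rerun with the flat preset.

The design power analysis computes the power to detect a 2x2
interaction of partial eta-squared 0.06 with 40 subjects per cell:
`f^2 = eta^2/(1-eta^2)`, noncentrality `lambda = f^2 * N` (N = 160),
`power = P(F'(1, N-4, lambda) > F_crit(0.05))` = 88.8%. Conventions
differ across tools — `lambda = f^2 * (N-4)` gives 88.0% — and the
implementation documents this one; discrepancies of about a point
against other software are expected.

## Problem sizes and numerical choices

The acceptance checks run the default 160-subject study with the `test`
sampler preset, ten 160-subject replications with a single 300+300
chain for effect-sign recovery, and 40-subject studies for the model
comparison checks — sizes chosen so the whole validation battery
completes in minutes on one core while keeping the design at its
documented dimensions. Numerical details: softmax is max-subtracted;
the logit transforms round-trip to 1e-12 across the support; the
vectorized likelihood agrees with the scalar path to 1e-10 (and with an
independently written oracle in the tests); every stochastic routine
takes an explicit seed, and all derived chain seeds are drawn below
2^31.
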