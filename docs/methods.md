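# Methods

This note documents the models, procedures and numerical choices behind the
package, and what its synthetic-data tests do and do not establish.

## Task model

Two session layouts are implemented. The *study1* layout has 320 trials in
four 80-trial blocks alternating between stable transitions (the
action→planet map is fixed) and variable transitions (every 6–14 trials one
of the two spaceship pairs swaps destination planets). The *study2* layout
has 280 trials with one stable map throughout. Stakes cues (×1 / ×5) are
assigned in a perfectly balanced, seeded permutation per block; the cue
multiplies points earned but, by design, not the reward signal the learner
sees (initialization of reward expectations at 4.5, the midpoint of the 0–9
display range, presumes the unmultiplied scale; stakes effects are carried
exclusively by the condition-specific model-based weights).

Rewards at each planet follow independent Gaussian random walks
(σ = 2) with reflecting boundaries at 0 and 9. Reflection acts on the
continuous latent value; the integer 0–9 reward shown and paid is the
rounded latent value. Walk start values are uniform on [0, 9] from the seed
(unbiased over the admissible range). The reward trajectories and the
first-stage-state sequence depend only on the session seed and are shared
across participants; stakes assignment and block order are counterbalanced
(4 cells for study1: block-order flip × stakes permutation; 2 for study2).
The first-stage-state sequence is a balanced random permutation — how the
original sequence was built is not documented anywhere we know of, and
balance avoids confounding state exposure. Swap gaps are uniform on
{6, …, 14} counted within a block; a pending swap is cancelled at a block
boundary, and the swapped pair is chosen uniformly per event.

## Learner

The hybrid agent is described in the README. Operational details that the
equations leave open, fixed here as part of the contract:

- **Within-trial update order**: (1) first-stage TD backup with r = 0 and
  the planet's *current* value as successor value, (2) transition update on
  observing the planet, (3) second-stage reward backup, whose prediction
  error also credits the first-stage pair through the eligibility trace
  (weight α·λ). Eligibility traces reset at every trial start, so λ only
  carries credit within a trial.
- **Missing responses**: a missing first-stage response cancels the trial —
  no likelihood term, no learning update, and the perseveration markers
  reset. A missing second-stage response forfeits the reward: the choice
  still contributes its likelihood term and the observed transition updates
  the transition beliefs, but no reward backup occurs.
- **Perseveration indicators** compare against the immediately preceding
  trial regardless of block, reset at session start and after a missing
  first-stage response. The response-key indicator uses each action's
  screen side on the current trial.
- **Stable blocks** use a transition learning rate of 1 (a single
  observation pins the deterministic map); the fitted η, η_CF apply only in
  variable blocks. In the study2 layout, where participants are instructed
  about a fixed structure, the transition matrix is initialized at the true
  map and never updated.

Generative simulation and likelihood replay share one update engine; tests
pin the replayed per-trial probabilities to the simulated ones exactly and
to an independently transcribed replay oracle at 1e-10.

## MAP fitting

Free parameters are optimized on unconstrained scales (logit for
unit-interval parameters, log for β) with L-BFGS-B (objective tolerance
1e-6, max 500 iterations per start); priors — Beta(2, 2) on unit-interval
parameters, Normal(0, 1) on π and ρ, Gamma(3, 0.2) on β — are evaluated on
the natural scale without a Jacobian term, so the optimum is the
natural-scale posterior mode and bounded estimates stay strictly interior.
The Gamma prior is read as shape–scale (mode 0.4), the convention of the
common MATLAB fitting toolboxes for this model family. Start points are
independent prior draws (100 by default); the highest converged posterior
wins, with ties broken by the lexicographically smallest parameter vector.
Choice probabilities that underflow at extreme β are floored at the
smallest positive double inside the likelihood so the objective stays
finite for the optimizer.

Model variants free subsets of {λ, η, η_CF, π, ρ} (α, β and all ω are
always free): the selected study1 variant frees λ, π, ρ with η = η_CF = 1;
the selected study2 variant frees π, ρ with λ = 0. AIC = 2k − 2·logL is
computed from the log-likelihood at the MAP point with k = number of free
parameters, and aggregated across participants by summation — the standard
group-level criterion; the mode of aggregation is a convention stated here
because alternatives (mean, vote) coincide in sign on our checks.

## Behavioral metrics

Task performance per trial is the obtained reward (before stakes
multiplication) minus the mean displayed reward of both planets that trial;
a uniformly random policy therefore scores 0 in expectation. Trials without
an obtained reward contribute nothing. The metacontrol index is
ω_high − ω_low per transition condition.

## Bayes factors

Correlation tests use a stretched beta prior on (−1, 1) with scale κ
(κ = 1 uniform) against the *exact* sampling density of the Pearson
correlation under bivariate normality (hypergeometric form), integrated by
adaptive quadrature at tolerance 1e-10; the Fisher-z approximation is not
accurate enough to reproduce two-decimal published values from rounded r.
One-sided tests renormalize the prior on the requested half-line and test
against the point null; this convention reproduces the published one-sided
values. Paired t tests use the JZS form: a Cauchy(0, √2/2 by default) prior
on the standardized effect, integrated against the noncentral-t density.
Both integrals are cross-checked against dense-grid quadrature oracles and
against pingouin's independent implementation in the tests.

Published-value comparisons are made after rounding to the displayed two
decimals, since the original values were computed from unrounded sample
correlations. One reported two-sided value (r = 0.06, n = 205, κ = 1/3:
printed 0.24) computes to 0.2317 from the rounded r — an unrounded
correlation near 0.064, which prints as 0.06, reproduces 0.24; the package
reports the value computed from the stated inputs.

## Bayesian design analysis

For each candidate true correlation ρ on a 0.01 grid, one population of
N = 1000 standardized score pairs is built whose *empirical* correlation
equals ρ exactly (orthogonalized-Gaussian construction — "true population
correlation" is treated as a property of the finite population, removing a
nuisance variance layer), and held fixed while samples of size n are drawn
without replacement. Each sample's correlation Bayes factor is classified
against the moderate-evidence cut-offs 3 and 1/3, and thresholds are the
smallest |ρ| reaching 80% alternative-evidence probability (resp. largest
|ρ| for null evidence). Because the Bayes factor depends on the data only
through (r, n), it is evaluated on a fine r grid once per configuration and
interpolated (cubic spline on log BF; interpolation error orders of
magnitude below the cut-off scale). The acceptance script uses 2,500
Monte-Carlo replicates per grid point (the tests 1,200); at these sizes the
threshold estimates are stable to one grid step.

## Synthetic cohorts

Per-participant generating parameters default to α ~ Beta(3, 3),
β ~ Gamma(4, 0.25), π, ρ ~ Normal(0, 0.3), ω_low ~ Beta(2, 3), and a
metacontrol effect ω_high − ω_low ~ Normal(0.15, 0.15) truncated to keep
ω_high in [0, 1] — wide, prior-compatible settings that put most
participants at or above the identity line in the ω_high-vs-ω_low plane.
No published distributional summary of fitted parameters exists to
calibrate against, so these are declared defaults, overridable through
`CohortSpec`.

NFC totals are generated directly at the scale level (German 16-item scale:
range −48…48, emulating observed mean 14.63 and SD 13.48; English 18-item
scale: range 18…90, mean 64.81, SD 9.68). They are built by the same
exact-correlation construction against the generating metacontrol index and
rescaled affinely — shrinking the spread when a draw would exceed the scale
bounds — so the target population correlation holds to floating-point
accuracy. Totals are therefore continuous rather than integer: rounding
would break the exactness contract the end-to-end tests rely on, and only
totals enter any analysis. Exclusion rules: strictly more than 20% missing
trials (first or second stage), and optionally strictly more than 95%
same-key responses.

## What the synthetic tests show — and don't

Passing recovery and null-pipeline tests show that *if* behavior is
generated by this model at realistic parameter settings, the fitting
pipeline identifies the model-based weights and their stakes difference
(rank correlations above 0.5 at 40 participants × 280 trials; metacontrol
bias within ±0.1), and that the inference layer does not manufacture
NFC–metacontrol associations where none exist. They do not validate the
model against human data: real participants exhibit lapses, drifts and
strategies outside this family, and the published analyses of the original
participant data (paired-test Bayes factors, condition performance means,
NFC descriptives) are reproducible only from the archived dataset, which
this package does not ingest.

## Problem sizes

The default test run fits 40 + 20×126 synthetic sessions with reduced
optimizer starts (10 and 2 respectively; the posterior is smooth and extra
starts change estimates negligibly — the multi-start monotonicity test
covers the contract) and uses 1,200 Monte-Carlo replicates per design-
analysis grid point. These sizes were chosen so the full pipeline exercises
every stage at statistically meaningful resolution while remaining
convenient to run repeatedly during development.
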