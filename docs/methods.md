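# Methods

## Models

Respondents are classified on K binary attributes; the latent classes are
the L = 2^K attribute profiles α_l, enumerated throughout in binary-counting
order with attribute 1 as the most significant bit (K = 2: 00, 01, 10, 11).
The order is a package convention — nothing downstream depends on it beyond
consistency — and is fixed so that every matrix index is reproducible.

**DINA** (conjunctive): item j requires the attributes with q_jk = 1; a
respondent mastering all of them succeeds with probability 1 − s_j, anyone
else with g_j.

**G-DINA** (saturated, identity link): item j has one free success
probability per reduced attribute profile, i.e. per combination of its
required attributes (2^{K*_j} values, stored directly as probabilities; the
delta main/interaction coefficients are a linear transform of this table and
are not kept internally, because the EM M-step is a closed-form proportion
in the per-class parameterization). DINA is the special case where all
non-full-mastery classes share one probability.

Item responses are conditionally independent given the profile, so the
likelihood of a response vector under a profile is the product over items of
P^x (1 − P)^{1−x}. It is evaluated in the log domain with success
probabilities clamped to [1e-10, 1 − 1e-10]; the clamp exists only inside
likelihood evaluation so that boundary estimates (which do occur in small
samples) cannot produce NaNs or −inf.

## Estimation

Marginal maximum likelihood by EM over the 2^K-class mixture:

- E-step: posterior class memberships from the current parameters, with the
  current class distribution π as empirical-Bayes prior; expected class
  masses and expected correct-response counts per reduced latent group.
- M-step: each item probability is the expected proportion correct in its
  latent group, clamped to [1e-4, 1 − 1e-4]; π is the mean posterior.
  A group with expected mass below 1e-8 keeps the previous iterate's value —
  with N = 100 and three-attribute items, empty latent groups are routine
  and the update must stay defined.

Starting values are deterministic so that every fit is reproducible without
a seed: g = s = 0.2 for DINA; for G-DINA, reduced-class probabilities linear
in the number of mastered required attributes from 0.2 to 0.8; π uniform.
Iteration stops when the largest absolute change over all item probabilities
and π entries falls below 1e-4, or the log-likelihood gain falls below 1e-7,
with a 1000-iteration cap. These are typical defaults for CDM software, and
the tau indices are insensitive to moderate changes in them. No
monotonicity constraint is imposed during estimation; monotonicity is only
enforced when *generating* parameters (below).

EAP classification thresholds the marginal posterior mastery probability at
0.5; a value of exactly 0.5 is classified as mastery (a tie rule has to be
fixed; ties have probability zero in continuous data anyway). MAP/MLE
classifiers are out of scope.

## Accuracy indices

τ_k averages, over respondents, the posterior probability of the *assigned*
category: α̂_ik P_ik + (1 − α̂_ik)(1 − P_ik), with P_ik the marginal
posterior mastery probability. τ averages the posterior mass of the
EAP-implied profile — the profile assembled from the attribute-wise
decisions, which may differ from the modal profile. Under EAP at threshold
0.5 every τ_k summand is max(P, 1 − P) ≥ 0.5, so τ_k ≥ 0.5 always; τ has no
such floor. Against known generating profiles, PCV is the proportion of
exact profile matches and PCA_k the per-attribute match proportions;
PCV ≤ min_k PCA_k on any input.

## The MI correction

The posterior at EM point estimates conditions on (δ̂, π̂) as if they were
the population values. The correction integrates the parameters out,
approximating their sampling distribution by nonparametric bootstrap:
resample the N respondents with replacement, refit the same model and
Q-matrix from the same deterministic initialization (warm-starting from the
original fit would artificially shrink the sampling distribution), and keep
the (δ̂_r, π̂_r) pair of each refit jointly, preserving their correlation.
The MI posterior is the average of the R per-draw posteriors; τ^MI and
τ_k^MI are then the same formulas applied to the MI posterior, with the
classifications held fixed at the original full-sample EAP estimates — the
correction targets the certainty about those classifications, not the
classifications themselves. When every draw equals the original estimates,
τ^MI = τ^EM to machine precision.

Nonconverged bootstrap refits are discarded and redrawn, capped at 5R
attempts; an ensemble therefore always contains R converged draws, and the
attempt count is reported as a diagnostic. Default R = 500 (conservative);
R = 100 is a documented fast mode whose Monte-Carlo SD on a worst-case
dataset (G-DINA, N = 100, IQ = 0.4) is about 0.01.

## Synthetic data

The generator reproduces a crossed design: attribute structure × model ×
test length × sample size × item quality.

- Built-in Q-matrices: a 30-item, K = 5 matrix with ten one-, two- and
  three-attribute items each; the J = 15 test is a fixed subset covering
  every attribute.
- Uniform structure: attributes iid Bernoulli(0.5) — equivalently uniform
  over the 2^K profiles (the two coincide exactly at prevalence 0.5).
  Higher-order structure: θ_i ~ N(0,1) and
  α_ik ~ Bernoulli(logistic(a(θ_i − b))) with a = 1.5, b = 0, giving 0.5
  prevalence and inter-attribute correlations near 0.3.
- Item quality IQ = 1 − P(0) − P(1) with P(0) = P(1) = (1 − IQ)/2 ∈
  {0.3, 0.2, 0.1}: the success probabilities of the all-zero and all-one
  reduced profiles are fixed at these endpoints. DINA items need nothing
  else (g = P(0), s = P(1)). G-DINA interior reduced-class probabilities are
  drawn uniformly on (P(0), 1 − P(1)) and accepted only if strictly
  increasing along the componentwise dominance order of reduced profiles
  (e.g. P(1,1) > P(1,0) > P(0,0)); rejection sampling keeps the draw exactly
  uniform on the constrained region. For three-attribute items the
  constraint is enforced over the full partial order, the natural
  generalization of the pairwise chains.
- Responses: x_ij ~ Bernoulli(P(x = 1 | α_i, δ_j)).

What the generator does *not* emulate: model or Q-matrix misspecification,
polytomous responses or attributes, missing data, and respondent-level
dependence beyond the higher-order trait. Passing benchmarks therefore show
the estimators behave as intended when the fitted model is the generating
model; they say nothing about robustness to misspecification.

## Replication harness and problem sizes

`run_condition` runs each replication end to end (generate → fit → classify
→ τ^EM → bootstrap MI → true accuracy) and aggregates means, RMSE and mean
absolute error of each estimator against the per-condition *mean* PCV/PCA
(the expected true accuracy under that condition), with τ_k RMSE averaged
over attributes. All randomness flows from one master seed through spawned
child sequences (data, per-replication bootstrap), so every summary is
bit-reproducible. Failed replications (a possibility with degenerate
resamples) are logged, counted and excluded.

The package defaults to paper-scale settings (100 replications, R = 500).
The shipped test suite and acceptance script run the same conditions at
20–50 replications and R = 100 — sizes chosen so the whole suite runs on a
laptop core in minutes — and check means within Monte-Carlo tolerance
(±0.05) rather than to print precision.

`stability_study` repeats the MI estimate on one fixed dataset with fresh
bootstrap seeds to measure Monte-Carlo variability per R; `subsample_study`
mirrors the real-data protocol: subsample N response vectors without
replacement, refit, and compare τ^EM / τ^MI against a benchmark that scores
the subsample's estimated profiles with posteriors computed under the
full-sample parameter estimates.

## Known limitations

- Identity link only; DINO, A-CDM and other reduced models are not
  implemented (DINA covers the reduced case studied here).
- No analytic standard errors: boundary estimates make the information
  matrix unreliable in exactly the small-sample settings of interest, which
  is why the bootstrap route exists.
- τ^MI remains slightly optimistic when true accuracy is very low
  (boundary estimates inside bootstrap refits); the harness exposes this
  rather than correcting it.
- EM finds local maxima from one deterministic start; multi-start
  estimation is not implemented.
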