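# Methods

This note documents the models, estimation machinery, defaults, numerical
choices, and known limitations of the `hexlearn` pipeline. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Task model

The shooting task is represented purely at the information level: per trial,
an opponent identity (A/B), that opponent's gun probability, a threat label
(high/low), an outcome `u` (gun = 1, phone = 0), a response (shoot /
withhold / missing), and a descriptive reaction time. The default design has
160 trials in probability blocks of 40, 15, 25, 25, 15, 40 with gun
probabilities 0.8/0.2 flipping at every block boundary; opponent B's
probability is complementary to A's on every trial.

The threat manipulation must be regular and orthogonal to the probability
schedule but its exact layout is a design choice. We default to alternating
20-trial high/low blocks starting with high (`threat_period`,
`threat_phase` configurable): the smallest regular period whose windows tile
all six probability blocks reasonably. Orthogonality of the *shown-opponent*
probability level to threat is achieved by balancing opponent A/B counts
within every contiguous (probability block × threat window) segment; the
test suite asserts |phi| < 0.05 for the default design. How opponents
interleave is not dictated by the task logic; we use seed-controlled
pseudo-random orders with balanced counts, which preserves per-opponent
contingencies while avoiding a deterministic alternation confound.

A residual, design-locked asymmetry remains: because probability blocks of
length 15 and 25 are not multiples of the threat period, each *opponent
stream's* exposure to p = 0.8 vs p = 0.2 trials is not exactly balanced
across threat conditions. Under a fixed schedule shared by all subjects this
produces small systematic condition differences in trajectory summaries
(mean mu_2, epsilon) even for agents generated with identical parameters in
both conditions. The null-calibration study quantifies the consequence: with
24-subject cohorts and the dual decision criterion, 90 % of null runs are
flagged clean. Any regular threat layout for these block lengths shares this
property; analyses of condition contrasts should keep it in mind.

## Observer models

Five learners filter the binary outcome stream into per-trial gun
predictions:

- **2-level HGF** (binary outcomes). Free parameters: `omega` (tonic
  log-volatility of the second-level Gaussian random walk; unbounded,
  typically −6…0; higher = faster belief updating) and `zeta` (decision
  noise, below). Initial belief `mu2_0 = 0`, initial variance
  `sigma2_0 = 1` (agnostic prior; configurable). The update cascade is the
  canonical one: prediction `mu_hat_1 = s(mu_2)`; precisions
  `pi_hat_2 = 1/(sigma_2 + e^omega)`, `pi_2 = pi_hat_2 + mu_hat_1(1 -
  mu_hat_1)`; precision-weighted prediction error `epsilon = (u -
  mu_hat_1)/pi_2`; `mu_2 <- mu_2 + epsilon`, `sigma_2 <- 1/pi_2`.
- **3-level HGF** adds a volatility level: the level-2 step variance is
  `exp(kappa * mu_3 + omega_2)`, and `mu_3` follows its own random walk
  (step variance `e^theta`) driven by volatility prediction errors, with the
  standard precision-weight update. `kappa` is fixed at 1 during fitting
  (the usual identification choice for binary data); `omega_2`, `theta` and
  `zeta` are free.
- **Rescorla–Wagner**: `V <- V + alpha (u - V)`, `alpha` in (0, 1].
- **K1** (incremental delta-bar-delta): the log learning rate `beta` is
  itself adapted, `beta <- beta + mu_meta * delta * h`, with learning-rate
  cap `alpha = min(exp(beta), 1)` and decaying eligibility trace
  `h <- h * max(0, 1 - alpha) + alpha * delta`. Free: `mu_meta`, `beta0`,
  `zeta`.
- **Kalman filter**: scalar filter with process noise `q >= 0` and
  observation noise `r_obs > 0`; gain `k = (s+q)/(s+q+r_obs)`. Free:
  `q`, `r_obs`, `zeta`.

**Decision model.** Predictions map to shoot probabilities through the
unit-square sigmoid `p = m^zeta / (m^zeta + (1-m)^zeta)`, the canonical
response model for binary HGF applications: `zeta = 1` is probability
matching, `zeta -> infinity` deterministic responding. It is computed in
log-space (`logistic(zeta * logit(m))`) so large `zeta` cannot overflow.
All probabilities are clamped to `[1e-12, 1 - 1e-12]` before logs.

**Per-opponent streams.** Because the task defines contingencies per
opponent, each subject carries two parallel belief trajectories (one per
opponent) sharing `omega` and `zeta`; each trial's prediction comes from the
shown opponent's stream. A pooled single-stream mode is available
(`opponents=None`) for designs without opponent structure.

## Estimation

Fitting is MAP with Gaussian priors in an unconstrained estimation space
(`omega` native; `zeta`, `mu_meta`, `q`, `r_obs` log-transformed; `alpha`
logit-transformed), multi-start BFGS (default 8 starts: prior means plus
seeded jitter of 0.5 prior SD; objective tolerance ~1e-6 gradient norm).
Missing responses are skipped in the likelihood; fits require at least 10
non-missing trials. The log model evidence is the Laplace approximation
`-J* + (d/2) ln 2 pi - (1/2) ln |H|` with `H` the central-finite-difference
Hessian at the optimum; a non-positive-definite Hessian is eigenvalue-
clipped at 1e-6 and flagged. The test suite checks the Laplace value against
a 2-D grid quadrature of the joint to 0.1 nats. MAP + Laplace was chosen
over a full variational scheme: the evidence enters only rank-based model
selection, and recovery studies show the approximation ranks the generating
model correctly.

Prior presets (estimation space):

| model | default | wide |
|---|---|---|
| hgf2 | omega ~ N(−3, 4), ln zeta ~ N(0, 1) | N(−3, 16), N(0, 4) |
| hgf3 | omega2 ~ N(−3, 4), theta ~ N(−6, 4), ln zeta ~ N(0, 1) | variances 16/16/4 |
| rw | logit alpha ~ N(0, 1), ln zeta ~ N(0, 1) | variances 4/4 |
| k1 | ln mu_meta ~ N(−2, 1), beta0 ~ N(−1.5, 1), ln zeta ~ N(0, 1) | variances 4 |
| kalman | ln q ~ N(−3, 1), ln r ~ N(−1, 1), ln zeta ~ N(0, 1) | variances 4 |

The `wide` preset is a loose-hyperprior surrogate for individual-differences
work; both presets are config-exposed, and priors include their
normalization constants so objective values are comparable across presets.

**Condition-wise parameters.** `omega` and `zeta` are made condition-
specific by refitting each threat condition's trial subsequence separately
(order preserved, opponent streams intact); `mu_2`, `sigma_2` and `epsilon`
are trajectory summaries averaged over that condition's trials. Refitting —
rather than splitting one fit's trajectory — is required for the fitted
parameters themselves to differ by condition.

**Exclusions.** Subjects are excluded when the missing-trial fraction
*strictly* exceeds 25 % (a 50 % sensitivity threshold is supported), and
when any designated parameter lies outside the sample mean ± 2 SD (moments
from the full sample, single pass, no iterative re-trimming; zero-variance
parameters are skipped with a warning). Every exclusion is logged.

## Model selection

Random-effects selection follows the variational Dirichlet scheme: iterate
`g_nk ∝ exp(lme_nk + psi(alpha_k) - psi(sum alpha))`,
`alpha_k = alpha0 + sum_n g_nk` to a 1e-6 sup-norm tolerance (error after
1e4 iterations), with `alpha0 = 1` (uniform). Exceedance probabilities are
Monte-Carlo estimates from 1e5 seeded Dirichlet draws; the K = 2 case is
tested against the closed-form Beta tail. A fixed-effects column-sum
companion is provided for diagnostics.

## Statistical layer

- 2×2 within-subject ANOVA: with two levels per factor every effect is a
  1-df contrast, so each F is computed as the squared paired t on the
  contrast scores (verified against an independent ANOVA implementation).
  ANOVA Bayes factors use the BIC approximation
  `BF10 = (1 - R^2)^{-n/2} / sqrt(n)` and are labelled as approximate.
- t-test Bayes factors are JZS (Cauchy scale sqrt(2)/2 on the standardized
  effect) by adaptive quadrature; the correlation Bayes factor uses the
  corresponding default linear-model form. "Default" priors are used because
  genuinely flat priors yield no finite Bayes factor.
- FDR is Benjamini–Hochberg step-up (via statsmodels), tested against the
  brute-force rule. Correlation power uses the Fisher-z approximation; note
  that its per-cent values truncate (not round) to the conventional printed
  figures at n = 188.
- Reliability: Cronbach's alpha by the variance decomposition; McDonald's
  omega_total from a single-factor ML fit delegated to the `sem` module
  (computed on the raw covariance, not z-scores).
- PCA: eigen-decomposition of the correlation matrix, listwise deletion
  (count of dropped rows reported), Kaiser criterion under `auto`.
- The pipeline-wide decision rule is dual: an effect is flagged only when
  p < 0.05 **and** BF10 > 3.

## Structural models

The SEM module fits CFA and MIMIC models by minimizing the normal-theory
discrepancy `F_ML = ln|Sigma| + tr(S Sigma^{-1}) - ln|S| - p` with analytic
gradients (L-BFGS-B, 10 jittered starts, residual variances log-
parameterized and bounded below at 1e-8 — estimates at that bound are
flagged as Heywood cases). Variables are z-scored by default. The covariate
block is saturated and fixed at its sample covariance; latent scale is
identified by unit residual latent variance (for a pure CFA this is exactly
unit latent variance), and the reported solution is standardized, which is
invariant to the identification choice. `chi^2 = (n-1) F_ML`; CFI uses the
independence baseline; `RMSEA = sqrt(max(chi^2 - df, 0)/(df (n-1)))`; SRMR
averages squared residuals of the correlation-metric covariances over the
lower triangle including the diagonal. Standard errors are Wald, from the
finite-difference Hessian of the analytic gradient.

In place of MCMC credible intervals, the second decision criterion for
structural paths is a nonparametric bootstrap percentile interval on the
standardized coefficients (default 2000 resamples; refits are warm-started
at the full-sample solution). This is a deliberate surrogate, not a
replication of a Bayesian computation. Missing data are handled listwise.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

- One standard-normal antisociality trait per construct, aggression and
  psychopathy correlated 0.64 by default.
- Condition-specific volatility: `omega_high ~ N(-2, 1)` and
  `omega_low ~ N(-4, 1)` by default (null cohorts set both means equal),
  `ln zeta ~ N(0.5, 0.4)`, initial belief `mu2_0 ~ N(0, 0.5)`. Trait
  couplings are standardized weights (defaults: −0.3 into omega, +0.3 into
  mu2_0, 0 into zeta). Couplings into the trajectory summaries sigma_2 and
  epsilon are induced *indirectly* through omega and the initial belief —
  those quantities are derived, not free — so recovery checks target signs,
  not magnitudes.
- Questionnaire subscales are congeneric: subscale = loading × trait +
  Gaussian residual, with loadings 0.65–0.80. Face-judgement (HIBT)
  responses follow a per-emotion logistic in expression intensity with
  slopes ordered anger > disgust > fear > joy and a trait-coupled subject
  bias.
- Missingness is 2 % MCAR by default; reaction times are log-normal
  (median 500 ms) and purely descriptive.

A second generator (`generate_mimic_cohort`) emits subject-level MIMIC data
directly — independent standardized learning-parameter summaries, a latent
trait regressed on them (default weights −0.20, +0.60, +0.35, +0.55, 0 for
omega, mu, sigma, epsilon, zeta), and four subscales — for validating the
structural layer in isolation. The weight magnitudes are chosen to be
admissible for independent standardized predictors (sum of squares < 1)
while preserving the signed pattern of interest.

What the generator does **not** emulate: real response-time structure,
non-Gaussian questionnaire distributions (bounded Likert scores, skew),
informative missingness, serial dependencies in responding beyond the
learner model, or demographic composition. Passing recovery tests therefore
establishes internal validity of the pipeline, not fidelity to any
particular human sample.

## Validation-study problem sizes

The acceptance script and the acceptance test suite run, per invocation:
model-selection recovery with 50 agents × 5 models; parameter recovery with
100 agents (reporting true-vs-fitted correlations for omega and zeta and
median generating-vs-refitted trajectory correlations for mu_2, sigma_2,
epsilon); structural sign recovery over 50 replicate MIMIC cohorts of
n = 500 with 200 bootstrap resamples each; 1e4 null simulations for t-test
calibration; and 50 null-pipeline runs of 24 subjects. These sizes are the
package's chosen operating points for routine validation; all are arguments
and can be scaled up.

## Known limitations

- The Laplace evidence can misrank models whose posteriors are strongly
  non-Gaussian; this does not surface in the recovery studies but is not
  ruled out for unusual response patterns.
- The SEM module covers ML estimation with continuous indicators only — no
  ordinal estimators, no multi-group constraints, no missing-data FIML.
- Protected exceedance probabilities and the Bayesian omnibus risk are
  documented extension points of the `bms` module, not implemented.
- The design-locked condition asymmetry described under *Task model* bounds
  how clean a fixed-schedule null calibration can be.
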