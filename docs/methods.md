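# Methods

## The model

`needsel` estimates a two-equation discrete-choice system for healthcare
needs and the barriers that leave them unmet, from long-format panel survey
data (one row per person-year).

**Selection (needs) equation.** A probit for whether person *i* experienced
any healthcare need in the reference year:

    y1 = 1(x1'b1 + e1 > 0),      e1 ~ N(0, 1).

**Conditional (barrier) equation.** Among person-years with needs, a
four-alternative multinomial probit: met needs (the reference alternative,
j = 1), financial difficulty (j = 2), time constraint (j = 3), lack of
caring and support (j = 4). Alternative j is chosen when its latent utility
`x2'b2j + e2j` is maximal, with `b2,1 = 0`. Working in differenced errors
`u_j = e2j - e2,1`, the joint law of `(e1, u2, u3, u4)` is multivariate
normal: `Var(e1) = 1`, `Cov(u) = Omega`, `Corr(e1, u_j) = rho_j`. The
cross-correlations `rho` are what make this a *sample-selection* model: the
barrier outcome is only observed for the selected (needs) subpopulation,
and correlated errors would otherwise bias the conditional equation.

**Scale normalization.** Utility differencing leaves Omega identified only
up to scale; we fix `Omega[0,0] = 2`. In the default **iid mode** Omega is
pinned to the differenced-iid structure (2 on the diagonal, 1 off), which
is exactly what iid standard-normal alternative-level errors imply, so
coefficients are on the familiar multinomial-probit scale and only the
three `rho_j` are estimated. An **unrestricted mode** frees Omega's
remaining Cholesky entries; without alternative-specific regressors those
parameters are weakly identified, which is why iid mode is the default.

## Outcome coding

Two raw survey answers drive the outcomes. Question 1 (any unmet need in
the past 12 months): code 1 = experienced at least once, 2 = did not
experience, 3 = no care of any kind needed. Question 2 (main reason, asked
when q1 = 1) has ten codes. Coding: `y1 = 1` iff q1 is 1 or 2; given needs,
q1 = 2 gives met needs, reason 1 gives financial difficulty, reason 7 gives
time constraint, and every other listed reason (2-6, 8-10) gives lack of
caring and support. Records with missing q1, or q1 = 1 with a missing
reason, cannot be coded and are dropped listwise with a plain-text
exclusion log; we deliberately do not default missing reasons to the
residual barrier group, since that would manufacture outcome information.

## Design matrices

Age enters centered (default: the unweighted pooled sample mean; the
generator and the reported fits center at 52.753 years). All polynomials
and gender interactions are built from the centered variable, which is what
keeps the variance inflation factors of the age block small (< 3 on the
synthetic default layout). For identification across the two equations the
default term lists differ: the selection equation carries gender-specific
age-squared terms but excludes the main age-squared, the man*age
interaction and alcohol consumption; the barrier equation carries the main
age-squared, man*age and man*age-squared but excludes exercise, obesity and
the woman-specific term. Estimation is on raw centered years; the x10 and
x1000 scalings of age rows are applied at reporting time only, so printed
tables are readable while the likelihood is never run on rescaled data.

## GHK simulation

Every likelihood contribution is a multivariate-normal orthant probability
in (at most) four dimensions: the non-needs probability is the exact normal
CDF, and each needs-and-alternative probability is
`P(e1 > -x1'b1, M_j u + c_j > 0)` for a full-rank 3x3 region matrix `M_j`
derived from utility differencing. These are simulated with the
Geweke-Hajivassiliou-Keane (GHK) recursive sampler:

- **Draws.** Scrambled Halton sequences with antithetic pairing,
  `n_draws = 200` per observation by default. Each observation receives its
  own consecutive block of the sequence (one sequence per outcome group).
  Per-observation draws matter: with a single draw set shared across
  observations the simulation error acts as a common distortion of the
  likelihood surface that does not shrink with n, and at 100-200 draws it
  is the same order as the likelihood's curvature in `rho`.
- **Common random numbers.** Draws are generated once per fit from the seed
  and reused for every parameter evaluation, so the simulated likelihood is
  a deterministic, smooth function of the parameters and results are
  bit-reproducible given `(seed, n_draws)`.
- **Numerics.** Truncated-normal sampling uses the survival-function form
  `z = -ndtri(t * u)` to stay accurate deep in tails; probabilities are
  floored at 1e-12 (with a counter) before taking logs.

The generic rectangle simulator (`ghk_mvn_rectangle`) accepts arbitrary
finite/infinite bounds; its 1-dimensional path returns the exact normal
probability. Against deterministic (Genz-type) integration, 500 draws give
maximum absolute errors around 1e-3 on random 4-dimensional rectangles.

## Estimation

Pooled weighted pseudo-maximum-likelihood: the longitudinal survey weights
multiply each person-year's log-likelihood contribution (weights are
normalized to mean one first, a pure rescaling), and within-person
dependence across waves is handled by the clustered sandwich variance
`A^-1 B A^-1` with `A` = minus the weighted Hessian and `B` the sum over
individuals of outer products of within-person summed weighted scores.
This pooled-plus-robust treatment — not random effects — is the intended
reading of "allowing for intra-individual correlation".

**Pilots.** Equation 1: weighted probit (IRLS via statsmodels GLM), with an
explicit error on perfect separation. Equation 2: weighted independent
multinomial probit in iid mode with `rho = 0`, whose choice probabilities
have an exact one-dimensional Gauss-Hermite representation
`P(j) = E_t[prod_{k!=j} Phi(t + eta_j - eta_k)]` (48 nodes).

**Optimizer.** All derivatives are taken in *index space*: for fixed draws
the log-likelihood of an observation depends on the parameters only through
seven scalars (the selection index, the three alternative indices, and the
three correlations), so central finite differences on those seven
coordinates — chained through the design matrices — deliver the full
gradient, per-observation scores, and the complete Hessian in about a
hundred likelihood sweeps, independent of the number of regressors. A
damped Newton ascent (Levenberg shift when the curvature is not negative
definite, Armijo backtracking line search, correlations transformed through
atanh, iterates kept a fixed margin inside the positive-definiteness
boundary) then converges in a handful of iterations from the pilot start.
A warm stage with 50 draws precedes the full-draw polish, under common
random numbers throughout. The line search guarantees the likelihood never
decreases across accepted iterates. The index derivatives at the optimum
are scale-free, so the sandwich variance is assembled from them at no extra
simulation cost. Internally, design columns are standardized to unit
spread during optimization (mapped back exactly afterwards) because the
age-squared columns are three orders of magnitude larger than the dummies.

**Identification of rho in practice.** With ~97% of person-years in the
needs group, the data carry very little information about the selection
correlations: profile log-likelihood differences across `rho` excursions of
+-0.5 are a handful of units even at 10,000 observations, and the
finite-sample maximizer can sit far from the truth without any detectable
misfit — in practice it tends to pin against the positive-definiteness
boundary of the joint error covariance, where the local quadratic
approximation (and hence any delta-method standard error for `rho`) is not
a valid uncertainty summary. Relatedly, the simulated surface is
microscopically rough along `rho` (observations with tiny conditional
probabilities have enormous higher log-derivatives), so all `rho`
derivatives are measured at a macro step (0.05, shrunk as needed to stay
positive definite) rather than the fine steps used for the linear indices.
The `fix_rho` option pins the correlations (e.g. at zero, which reduces
the model exactly to probit x independent MNP and reproduces the pilots);
the free-rho fit is the default, but its `rho` estimates should be treated
as set-identified in data of this kind, and recovery claims are made for
the regression coefficients only.

**Diagnostics.** AIC = -2 loglik + 2k, BIC = -2 loglik + k ln(n) with n =
observations by default (configurable to individuals). The
Hosmer-Lemeshow test is run on an *unweighted* refit of the selection
probit (the grouped chi-square reference distribution assumes unweighted
sampling); risk deciles, statistic `sum (O - n pbar)^2 / (n pbar (1-pbar))`,
df = groups - 2, with degenerate groups merged into their neighbor. Under a
correctly specified probit its empirical size at the 5% level is within
Monte-Carlo error of 5% (500-replication check). p-values throughout use
the normal reference (large-sample z tests).

## Average adjusted probabilities

For each grid point (gender, age in 20-90 by 5), *every* observation's
gender and age — and every term derived from them, the only internally
coherent choice — are overwritten; other covariates stay at their observed
values; the weighted mean of the predicted probabilities is the AAP.
Joint probabilities `P(needs & barrier)` are the default (they sum to the
unmet-needs AAP by construction); conditional-on-needs probabilities are
available behind a flag and nearly coincide when the needs probability is
close to one. Confidence bands use the delta method: the Jacobian of each
AAP with respect to the free parameters (index-space finite differences
chained through the grid design) times the cluster-robust covariance; the
needs-AAP gradient is analytic. CI bounds are clipped to [0, 1].

## Synthetic data generator

The generator emulates the structure of a restricted-access national health
panel so the whole pipeline is testable:

- **Covariates.** Baseline draws match the published pooled marginals (man
  0.462; age truncated-normal on [19, 95] with SD 17.668 and location tuned
  so the *truncated* mean is 52.753 — truncation compresses the realized SD
  to about 15.9; fourteen binaries; occupation and income as three-level
  categoricals). Covariates are drawn independently because only marginals
  are published. Time-varying covariates are redrawn from their marginal
  with probability 0.05 per wave (the panel's variables are described as
  time-varying but no dynamics are published); age increments by one.
- **Panel structure.** Five annual waves from 2014; monotone dropout with
  probability 0.02 per wave, giving expected last-wave retention 0.98^4 ≈
  0.922. Weights are log-normal (sigma = 0.3), normalized to mean one.
- **Outcomes.** Drawn from the latent system itself with the published
  coefficient table as the truth (display scaling undone, age centered at
  52.753) and default `rho = (0.3, 0.3, 0.3)` — the true cross-equation
  correlations are unknowable from published output, so this default is an
  explicit, configurable stand-in. Raw q1/q2 answer codes are reconstructed
  by inverting the outcome coding (the residual barrier group gets a random
  non-{1,7} reason code), so coding round-trips exactly.

**What the generator does not emulate,** and hence what passing tests do
not establish about real data: cross-covariate correlation (real age, job
status and health are strongly dependent, which changes outcome prevalences
— the synthetic unmet-needs share is ~25% of needs versus ~12% in the real
survey, mostly through the time-constraint category), informative
attrition, design-based weight structure, and any measurement error. Tests
against the generator validate the *estimator*, not the substantive
published findings.

## Problem sizes and numerical defaults

The packaged checks use 2,000 individuals x 5 waves (~9,600 person-years)
with 200 draws for parameter recovery, and 1,000 individuals for the
factorization check — sizes at which a full fit takes a few minutes on one
core. At that scale the sampling-noise floor of the mean absolute
coefficient error is about 0.06-0.08 (only ~150 non-needs person-years
inform the 20 selection coefficients, and each barrier equation sees
300-1,000 events), an order of magnitude above the simulation error of the
GHK at 200 draws. Finite-difference steps: 1e-5 / 3e-4 (first / second
derivatives of the linear indices), 0.05 for the correlations (see above);
Newton stops when the expected quadratic improvement falls below
1e-7·(1+|loglik|) or when repeated backtracked micro-steps show the
optimizer is inside the simulation noise floor.

## Limitations

- No analytic GHK gradients (finite differences in index space suffice at
  these problem sizes) and no random-effects variant.
- The unrestricted-Omega mode is functional but weakly identified without
  alternative-specific regressors; treat its covariance estimates as
  exploratory.
- Full design-based (two-stage cluster) variance is out of scope; only
  weights plus individual-level clustering are implemented.
- The Heckman two-step and multinomial logit are deliberately absent as
  headline estimators (Mill's-ratio collinearity and the independence of
  irrelevant alternatives, respectively); the pilots play their comparator
  role.
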