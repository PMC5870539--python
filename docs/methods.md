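# Methods

## The model and its assumptions

`longmed` plans and analyses lower-level (1-1-1) mediation in longitudinal
designs: the exposure X, mediator M and outcome Y are all measured at the
occasion level, while subject-level heterogeneity enters through random
intercepts in the M- and Y-equations.  For subject j = 1..J and occasion
i = 1..m,

    M_ij = gamma_3 + u3_j + beta_a X_ij + e3_ij,
    Y_ij = gamma_2 + u2_j + beta_c' X_ij + beta_b M_ij + e2_ij,

with u2_j ~ N(0, tau^2), u3_j ~ N(0, tau^2) independent across subjects and
equations, and e2_ij, e3_ij ~ N(0, sigma^2) independent across occasions.
The slopes are fixed effects (no random slopes), the design is balanced and
complete, and errors are Gaussian.  The estimand is the indirect effect
beta_a * beta_b; the total-effect regression of Y on X alone is not needed by
any of the tests and is not fitted.  The direct effect beta_c' is estimated
freely in the Y-equation (standard practice) and defaults to zero in the
generator, the convention of classical mediation power studies.

## Generator conventions

Two choices in the data-generating process matter more than anything else
for the resulting power surface, and both are explicit config fields.

**Exposure law (`x_mode`).**  The default, `subject_constant`, draws one
X_j ~ N(0,1) per subject and repeats it across occasions — the randomized,
time-invariant treatment scenario.  `iid_standard_normal` draws X fresh at
every occasion (a within-subject, time-varying exposure, e.g. cross-over
designs).  The choice is consequential: with a time-varying exposure the
a-path is estimated from within-subject contrasts and its precision is
essentially unaffected by the intraclass correlation, whereas a
subject-constant exposure makes the a-path a between-subject regression
whose information per subject is 1/(tau^2 + sigma^2/m).  Reference
sample-size tables for this design encode the subject-constant convention —
their high-ICC cells show the between-subject information signature (power
nearly independent of beta_b when beta_a is small) — so it is the default.

**Variance convention (`variance_mode`).**  Both equations share one
correlation parameter `icc` in [0, 1) that sets the between-subject variance
tau^2 = icc.  The default `unit_within` fixes the occasion-level error
variance at sigma^2 = 1, so the marginal error variance is 1 + icc and the
error intraclass correlation is icc/(1 + icc).  The published sample-size
tables this package reproduces were generated under that convention: their
power surface matches it cell by cell (verified across ICC 0.1-0.9, m = 2-5,
Sobel/product/bootstrap), while the strict normalization is incompatible
with their high-ICC entries.  The alternative `unit_marginal` sets
sigma^2 = 1 - icc, so tau^2 + sigma^2 = 1 and the error ICC is exactly
`icc`; use it when the textbook normalization is wanted.  All distributional
identities used in the tests (within-subject covariance tau^2, Var(M) =
beta_a^2 + tau^2 + sigma^2, ANOVA ICC recovery) hold under their respective
conventions.

What the generator does **not** emulate: unbalanced or incomplete panels,
non-Gaussian errors, time trends, correlated random effects between the M-
and Y-equations, random slopes, and measurement error in X.  Passing tests
therefore certify the Monte-Carlo machinery under the stated model, not
robustness of the three tests to violations of it.

## Estimation

For a balanced design the random-intercept covariance per subject is
compound-symmetric, V = sigma^2 I + tau^2 J_m, with eigenvalues
lambda_1 = sigma^2 + m tau^2 (between) and lambda_2 = sigma^2 (within).
The marginal Gaussian likelihood separates into between- and within-subject
least squares coupled through the shared coefficients, and is profiled down
to a one-dimensional search over gamma = lambda_2/lambda_1 in (0, 1]:

    beta(gamma) = (W + gamma B)^{-1} (w_xy + gamma b_xy),
    lambda_1(gamma) = (SSW/gamma + SSB) / (J m),

where W, B are within/between cross-product matrices.  The search runs on
log(gamma): a 25-point coarse grid, 48 golden-section iterations, then a
parabolic polish on a wide stencil (half-width 1e-3 in log gamma).  The
polish matters for reproducibility: the golden-section endpoint wanders
inside the machine-flat region of the objective, while the parabola vertex
is a smooth function of the data, giving location-shift invariance of all
estimates at the 1e-13 level.  gamma = 1 is the tau^2 = 0 boundary — a
legitimate ML optimum, reported as tau_sq_hat = 0 with converged=True;
estimates below 1e-10 are truncated to zero and the fit is redone at the
boundary.  Estimation is ML by default; REML is available
(`fit_random_intercept(..., reml=True)`, same profiled closed form with the
restricted criterion) but ML-vs-REML differences are far below Monte-Carlo
resolution at the sample sizes involved, so the power machinery uses ML.

Fixed-effect standard errors are the exact inverse Fisher information
(X' V^{-1} X)^{-1} at the ML variance estimates (verified against a dense
matrix computation at 1e-8); note that profiled-Hessian implementations
(e.g. statsmodels MixedLM `bse`) can differ from this by a percent or two in
small samples.  Coefficients, variance components and the log-likelihood
agree with an independent mixed-model routine to ~1e-5 and with a
brute-force (tau^2, sigma^2) grid maximization at 1e-3 resolution.

All columns are grand-mean centered before cross-products are formed (the
model is shift-invariant; raw cross-products lose precision when means are
large), and the intercept is restored afterwards using the balanced-design
orthogonality of the centered intercept.

Everything is vectorized across batches: one power evaluation fits all
replicates simultaneously, and a bootstrap fit is a sum of per-subject
cross-product blocks over the resampled ids, so a 300-replicate x
300-resample bootstrap power estimate takes ~10-20 s on one CPU.

## The three tests

* **Sobel.**  CI = ab ± z_{1-alpha/2} * sqrt(se_a^2 b^2 + se_b^2 a^2)
  (first-order delta method).  Known to be conservative because the product
  of two estimated coefficients is skewed, not normal.
* **Distribution of the product.**  Critical values delta_lower and
  delta_upper are obtained by simulating P = Z1 Z2 with Z1 ~ N(z_a, 1),
  Z2 ~ N(z_b, 1) at the standardized path estimates (1e5 draws by default),
  taking the alpha/2 and 1-alpha/2 empirical quantiles, and standardizing
  their distances from the center z_a z_b by sd(P) = sqrt(z_a^2+z_b^2+1).
  The CI is (ab - delta_lower * se, ab + delta_upper * se) with the
  delta-method se; the deltas approach z_{1-alpha/2} in the large-|z| limit
  (the residual skewness of the product decays like 2.12/z, so at z = 50
  the upper delta still sits 0.02 above 1.96).  In Monte-Carlo power loops
  the deltas are cached on (z_a, z_b) rounded to two decimals, with the
  draw seed derived deterministically from the cache key, which bounds cost
  without affecting results at power-table resolution.
* **Percentile cases bootstrap.**  Resamples J subject ids with replacement
  and copies each drawn subject's complete records (upper level only — the
  recommended scheme when m is small; a both-levels option exists but is
  off by default).  Duplicate subjects act as distinct groups, preserving J
  groups in every bootstrap likelihood.  The CI is the (alpha/2,
  1-alpha/2) empirical percentile interval of the bootstrap ab estimates
  with type-7 (linear) interpolation, fixed for bit-stability across
  platforms.  Bootstrap fits that fail to produce finite estimates are
  dropped; if more than 20% fail the interval is flagged unreliable, and
  replicates whose bootstrap distribution is >20% degenerate are dropped
  from power denominators (in practice the closed-form fitter makes
  failures vanishingly rare — the drop counters are diagnostics, not an
  active correction).

## Power and sample size

Power is the proportion of simulated replicates whose interval excludes
zero, with binomial Monte-Carlo standard error sqrt(p(1-p)/n_reps).
Replicate r derives its generator from (seed, stream, r), so any replicate
can be regenerated in isolation and results do not depend on execution
order or batching.  Type-I error uses the same machinery and simply refuses
configurations in which both paths are nonzero.

The sample-size search brackets the 80% target by doubling/halving from a
closed-form initial guess (Sobel normal approximation with the per-subject
informations 1/(tau^2 + sigma^2/m) for the a-path under a subject-constant
exposure and m for the b-path), then bisects on integers.  Because the adopted
convention is "the power nearest the target", the search returns whichever
bracketing integer has estimated power closest to the target (ties to the
smaller n) — this occasionally returns an n whose power is slightly below
0.80, exactly as some published cells do.  Candidate sample sizes share the
same replicate seed stream (common random numbers), which removes most
search noise and makes the whole search deterministic given the master
seed.  Default scales are 1000 replicates and 500
bootstrap resamples; grid runs offer a `smoke` profile (300/300) whose
wider binomial noise is meant for exploration and CI bands, not for tables.

Remaining Monte-Carlo noise on a returned n at 1000 replicates is roughly
±4-6% of n (the power curve's slope near 0.80 maps ±0.012 of power noise
into that range), which is the right yardstick when comparing two searches
or a search against a published table entry.

## Numerical and design choices

* gamma is bounded in [1e-8, 1]; ICC arbitrarily close to 1 is representable.
* Percentile interpolation: type-7, chosen once (the convention is not
  standardized across software; any fixed choice differs by O(1/B)).
* Sample-size search bounds: n in [3, 1e6]; an unreachable target raises an
  error reporting the boundary powers rather than returning a guess.
* The effect-size letter grid S/H/M/L = 0.14/0.26/0.39/0.59 (Z = 0 for null
  scenarios) follows the standard mediation power literature.
* Degenerate fits (zero Sobel se with nonzero estimate) warn and return a
  point interval rather than erroring, so power loops never abort.

## Known limitations

* Only balanced, complete designs; the cases bootstrap and the closed-form
  likelihood both rely on equal cluster sizes.
* The single `icc` governs both equations; unequal tau^2 across equations
  is not exposed (the reference design does not vary them independently).
* The product-method cache rounds z-scores to 0.01, so two fits inside the
  same power run whose z-scores differ by less than the rounding share
  critical values; at 1e5 draws this is far below rejection-decision
  resolution, but exact per-fit quantiles are available through
  `product_ci(..., seed=...)`, which bypasses the cache.
* The closed-form initial guess for the search is deliberately crude (the
  Sobel normal approximation overstates power in small-z regimes); it only
  positions the bracket and never affects the returned n beyond runtime.
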