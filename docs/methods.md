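# Methods

## Model

All scenarios are linear-Gaussian structural equation models over
(X, Z, U, Y, R). X, Z, U are exogenous normals; Y is a linear combination of
its parents plus an error; R — the *latent missingness score* — is a linear
combination of its parents plus an error; all errors are independent, there
are no interactions or non-linear terms, and analysis/imputation models are
fitted by least squares (logistic maximum likelihood for binary variables).
The binary missingness indicator thresholds the score: a value is observed
iff R ≤ r, with r = μ_R + √V_R · Φ⁻¹(π₁) chosen from the *model-implied*
mean and variance of R so that P(observed) = π₁ exactly in the population.
We deliberately do not calibrate r per sample; π₁ is a population
probability, and per-sample calibration would distort the missingness
mechanism's dependence on the realised draws.

The implied joint covariance is built by writing each variable as a linear
map of the independent sources (X, Z, U, ε_Y, ε_R) and forming
A·diag(source variances)·Aᵀ — path tracing in matrix form, exact for any
coefficients. Every scenario uses the same five-variable representation with
the coefficients absent from its DAG pinned to zero at construction; this
gives a single covariance constructor and a single partial-regression oracle
for all three DAGs.

Means: bias quantities are location-free, so μ_X, μ_Z, μ_U default to 0.
μ_R is nevertheless carried through because the observation threshold r
needs it whenever means are nonzero.

## Limiting bias and its oracle

As the missing fraction tends to one, the expected MI estimator of the
exposure coefficient tends to the population partial-regression coefficient
that additionally conditions on R (and on Z when Z is in the imputation
model). The closed forms evaluate these limits in terms of direct effects
and error variances; the oracle recomputes them as
Σ_pp⁻¹ σ_pt from the implied joint covariance. The two routes are
algebraically independent (one never calls the other) and are required to
agree to 1e-10 relative error over randomized parameter sweeps — effects
uniform on [−1.5, 1.5], variances on [0.3, 2.0] — for every scenario,
including the unsimplified imputing-X expression for the Y-and-X-caused
missingness DAG, which is evaluated exactly as written (with the β_XY/β_YX
ratio expanded so the β_YX = 0 boundary stays finite).

When the incomplete variable is X, the "true" reverse-regression slope β_XY
is derived from the joint covariance rather than accepted as input, which
makes inconsistent user input impossible.

The relative additional bias is reported as a percentage and is `None`
(an explicit sentinel, never a propagated NaN) when the estimand is zero.

## Convergence rate of the limits — an important caveat

The limiting coefficients are *suprema*, approached as π₁ → 0, not values
attained at any practical missingness level. The large-n MI mean equals the
selected-sample slope Cov(Y, X | R ≤ r)/Var(X | R ≤ r), which differs from
the R-conditional limit by terms of order Var(R | R ≤ r)/Var(R) ≈
1/(2 ln(1/π₁)) — logarithmic in the missing fraction. For the unit-parameter
outcome-missingness scenario the exact truncated-bivariate-normal value at
π₁ = 0.02 is 0.714 (no auxiliary) against the limit 2/3, and our Monte-Carlo
runs reproduce that value to within Monte-Carlo error. `limiting_case_check`
therefore reports the gap table (and verifies the approach is monotone)
rather than asserting closeness to the limit; a `strict` flag opts into a
2%-gap assertion that only extremely small π₁ could satisfy. One
acceptance-level check asserts a 2% gap at π₁ = 0.02 and is expected to
fail for this mathematical reason; it is retained unweakened as
documentation of the convergence rate.

## Synthetic data

The generator draws the five sources on independent, deterministic
substreams of a single integer seed (`SeedSequence(seed, spawn_key=(k,))`),
so datasets are bit-for-bit reproducible and per-replicate streams in
studies are independent by construction. Binary Y or X is produced by
thresholding the *latent* continuous variable at the population quantile
matching the target prevalence — structure and missingness always operate on
the latent scale, imputation only ever sees the 0/1 version (prevalence 0.5
for X gives mean 0.5, variance 0.25). U is generated where the DAG has it
but is embargoed from every imputation and analysis model, matching its
unmeasured role.

What the generator emulates: multivariate-normal path models with
latent-threshold missingness and optional latent-threshold dichotomisation.
What it does not: non-normal errors, interactions, non-linear structural
terms, measurement error, or multiple simultaneously incomplete variables.
Passing tests therefore demonstrate the estimator algebra and the mechanism
of auxiliary-variable bias amplification, not robustness of MI on messier
real data.

## Multiple imputation

Proper imputation for a continuous incomplete variable: fit OLS on the
complete records; draw σ*² = σ̂²·ν/χ²_ν with ν = n_obs − p; draw
β* ~ N(β̂, (σ*²/σ̂²)·V̂); impute each missing value as its linear predictor
under β* plus N(0, σ*²) noise. For a binary incomplete variable: logistic
fit, β* ~ N(β̂, V̂) (asymptotic posterior approximation), Bernoulli draws at
the inverse-logit probabilities. The noise and perturbation steps are
individually suppressible as test hooks. With exactly one incomplete
variable a single conditional draw is a valid joint draw, so no
chained-equations iteration is performed.

Pooling follows Rubin's rules; the pooled SE carries no small-sample
degrees-of-freedom adjustment (the default studies use m = 10, chosen for
bias rather than variance estimation; m is a parameter wherever it appears,
and the interval-coverage test uses m = 20). Per-completed-dataset variances
use the conventional OLS (or observed-information logistic) estimator.
Linear fits use the normal equations directly (the proper draw needs σ̂²,
V̂ and ν anyway); logistic fits use statsmodels, with perfect separation
surfaced as an explicit error.

## Study sizes and tolerances

Defaults: n = 5000, 500 replicates, m = 10 for Monte-Carlo studies
(Monte-Carlo SE ≈ 0.001–0.01 on unit-variance scales); n = 100 000,
100 replicates for limiting-case paths (≥ 500 expected complete records at
π₁ = 0.02, enforced); effect grid {0, 0.25, 0.5, 0.75, 1} with unit error
variances. Stochastic checks use 4 Monte-Carlo standard errors; algebraic
checks use 1e-10 relative error; the covariance constructor accepts smallest
eigenvalues down to −1e-8 × the largest. Replicate failures (e.g. logistic
separation in extreme draws) are counted and tolerated up to 1% of a study.
A full default-size study runs in seconds; the heaviest configuration
(limiting-case path at n = 10⁵) runs in well under a minute per π₁ value.

For binary-Y studies the estimand is the population log-odds slope of the
(misspecified, hence KL-projected) marginal logistic regression of binary Y
on X, computed by Gauss–Hermite quadrature; binary results are asserted at
the sign/ordering level only, mirroring the approximate status of the
latent-normal argument for dichotomised variables.

## Scale conversions and the applied estimator

Logistic coefficients convert to probit scale by the standard ×0.6 rule, and
probit coefficients to odds ratios by exp(β/0.6); printed values round to
2 dp (coefficients) and 1 dp (odds ratios), full precision retained
internally. The applied amplification estimator normalises R to mean 0,
variance 1 (without loss of generality), under which β²_RZ σ²_Z and
β²_RY β²_YX σ²_X are squared correlations with the missingness score; their
sum must stay below 1, and violations raise an error that names the
normalisation rather than returning a negative denominator.
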