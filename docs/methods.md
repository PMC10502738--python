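# Methods

## Model

For individual *i* and marker *j* the hazard of the event (an age at onset,
e.g. age at natural menopause) is

    lambda_i(t) = lambda_0(t) * exp( x_ij * beta_j(t) + g_ik * xi_j + z_i' delta_j ),
    beta_j(t)   = beta_j0 + beta_j1 * (t - t0),

with `x_ij` the marker dosage standardized to mean 0, SD 1 on the analysis
sample; `g_ik` an optional leave-one-chromosome-out (LOCO) polygenic offset
(the chromosome *k* is the one carrying marker *j*); and `z_i` optional
covariates. The baseline hazard `lambda_0` is profiled out by the partial
likelihood and never estimated as a parameter (an optional Breslow estimate
backs the survival-curve utility). A linear effect trajectory keeps the
variance of `beta(t)` exact — no expansion approximations — and is the
shape that fits age-at-onset data well in practice; other parametric shapes
would slot into the same framework but are not implemented.

Each marker is fit *marginally*: `xi_j` and `delta_j` are re-estimated
jointly with `(beta_j0, beta_j1)` for every marker, so marker fits are
mutually independent and trivially parallel.

## Fitting

The marker contributes two partial-likelihood covariates, `x` and
`x*(t - t0)` evaluated at each risk-set event age. Newton–Raphson with the
analytic gradient and Hessian maximizes the log partial likelihood; Efron's
tie correction is the default (ages are often recorded in whole or
fractional years), Breslow selectable. Step-halving (up to 10 halvings)
keeps the log likelihood non-decreasing; convergence is declared when its
relative change drops below 1e-8 (default; max 50 iterations), after which
two cheap refinement steps sharpen the maximizer to near machine precision.
The `(beta0, beta1)` covariance block is the corresponding 2x2 block of the
inverse observed information of the *full* parameter vector.

Two degeneracies are flagged rather than silently reported. If `|beta|`
exceeds 50 on the standardized scale, or the likelihood flattens while the
Newton step is still large (the signature of a maximizer at infinity /
complete separation), the fit carries a `monotone_likelihood` flag. A
constant dosage raises `MonomorphicMarker`; a cohort without events raises
`NoEvents`.

Because a standardized hard-call dosage takes only a handful of distinct
values, the risk-set sums factor per dosage level into per-group suffix
sums, making one Newton iteration O(n · G · q²) (G = dosage levels,
q = static covariates) instead of O(n · #events). A dense chunked path
covers continuous dosages; the two paths agree to machine precision in the
test suite. All exponentials carry a per-event shift so trial steps far
from the optimum cannot overflow.

## Age-specific testing

With `v(t) = var0 + (t-t0)^2 var1 + 2 (t-t0) cov01`, the Wald trajectory is
`chi2(t) = beta(t)^2 / v(t)`. Its stationary points are closed-form:

    t1* = -beta0/beta1 + t0                                     (global minimum, chi2 = 0)
    t2* = (beta0*cov01 - beta1*var0)/(beta1*cov01 - beta0*var1) + t0   (global maximum)

and `chi2(t) -> beta1^2/var1` as `t -> +/-infinity`. `chi2(t2*)` equals the
quadratic form of `(beta0, beta1)` in the inverse covariance block — the
joint 2-df Wald statistic — which is why its null law is chi-squared(2) and
why `p = exp(-chi2/2)` is a valid p-value at the maximum. Since the
statistic at any age is bounded by the maximum, the same quantiles bound
the type-I error at every age simultaneously: testing a whole grid of ages
costs no multiplicity correction. The slope test `beta1^2/var1` is referred
to the same df = 2 distribution, which is conservative for a one-parameter
hypothesis; this mirrors how the framework treats every statistic as a
point on the one trajectory.

Degeneracy handling: `|beta1| < 1e-12` sends `t1*` to infinity;
`|beta1*cov01 - beta0*var1| < 1e-12` sends `t2*` to infinity, where the
supremum is the limiting slope statistic. `beta0 = beta1 = 0` exactly is a
`DegenerateFit` (trajectory identically zero); the maximum-evidence test
maps it to `chi2 = 0, p = 1`.

Three user-facing tests:

* **grid test** — `chi2(t)` at ages 41, 43, ..., 55 (configurable);
* **maximum evidence** — `chi2(t2*)` if `t2*` lies in the open window
  (45, 52), otherwise the larger endpoint value (the window avoids
  over-interpreting the linear extrapolation at uncommon ages; on an exact
  endpoint tie the lower age is reported — consequence-free for p-values);
* **slope test** — `H0: beta1 = 0` for an age-specific effect per se.

Evidence tiers for the slope: none (p ≥ 0.05), weak (p < 0.05), moderate
(p < 5e-8), strong (moderate + replication p < 0.05 with the same slope
sign).

P-values are also carried as log10 values: `exp(-chi2/2)` underflows
float64 near `chi2 ≈ 1488`, far below genome-wide magnitudes, so serialized
records keep `log10_p` columns alongside `p`.

## LOCO offset

Marker effects for the polygenic predictor come from a ridge-penalized
right-censored Weibull accelerated failure-time model of log age,
`E[log y] = mu + X beta + Z delta`, `Var[log y] = pi^2/(6 alpha^2)`,
maximized by L-BFGS-B with the analytic gradient (intercept, covariates and
shape `alpha` unpenalized). The single-Gaussian ridge prior is a deliberate
design choice: the CAMP testing layer needs a reasonable offset to absorb
polygenic background, not posterior inference over sparse mixture priors,
and a penalized MLE keeps the package dependency-free and fast. The penalty
can be chosen by k-fold cross-validated held-out AFT log-likelihood
(`select_ridge_penalty`); a value of the order of the marker count is a
sensible default for genome-wide panels. Predictors are
`g_ik = sum_{j not on k} x_ij beta_j`, centered per column (centering only
shifts the profiled baseline, never the tested effects). Externally
computed predictors (e.g. from a full Bayesian model) can be supplied as a
TSV and bypass this module entirely.

## Simulator

The generator emulates a biobank-like age-at-onset cohort. Dosages are
independent Binomial(2, maf) across markers (MAFs uniform on a configurable
range, default 0.05–0.5), laid out over ≥2 chromosomes and standardized.
Event ages follow the generative hazard with a shifted-Weibull baseline;
the defaults k = 12, b = 52 years put the median event age near 50.4 and
roughly nine in ten events between 45 and 55, the profile of age at natural
menopause. Assessment ages Uniform(40, 70) right-censor the cohort
(interview-age censoring), and the standard phenotype window [33, 65] is
applied: event ages outside it are excluded, censoring ages above 65
truncated to 65 (censored individuals still contribute risk time inside the
modeled range; the exclusion rule itself is stated only for event ages, so
truncation is this package's documented, configurable choice). No delayed
entry / left truncation is modeled: the risk set at age t is everyone with
recorded age ≥ t.

Event times invert `Lambda_i(T) = -ln U`. Because the log hazard ratio is
linear in age, the integrand is smooth and the cumulative hazard is
integrated with Simpson's rule on 0.1-year panels and inverted by bisection
to 1e-8 years; individuals sharing a causal-genotype profile share one
cumulative-hazard grid. Targets beyond the 90-year integration horizon
become censored observations. Overflowing hazards (implausible effect
sizes) raise `NonFiniteHazard`.

What the simulator does *not* emulate: linkage disequilibrium between
markers (independence by construction — the clumping tests build their own
correlated blocks), population structure, genotype missingness patterns,
X-chromosome dosage compensation, or informative censoring. Passing tests
therefore validate the estimator and the distribution theory under clean
sampling, not robustness to those real-data features.

The fixture cohort `fixture_d1` (seed 20230804, n = 200, m = 10, one causal
SNP with beta0 = 0.3, beta1 = -0.02 at t0 = 49) is the deterministic anchor
of the test suite.

## Clumping

Greedy p-value-ordered clumping with a symmetric 1 Mb window, index
threshold 5e-8, member r² ≥ 0.05 and no member p threshold. LD is the
squared Pearson correlation of the provided standardized dosages — never an
external reference panel — and clumps never cross chromosomes. Ties in p
break deterministically by (chromosome, position). Conditional/joint
re-analysis of clumps (COJO-style) is out of scope; published locus counts
built on such a step sit on top of clumping like this.

## Numerical and design choices

* `t0 = 49` by default; reparameterization invariance is exact (refits at
  different `t0` give identical `chi2(t)` curves), so the choice is
  cosmetic.
* Missing genotypes are mean-imputed per marker before standardization;
  markers with MAF ≤ 2e-4 or zero variance are dropped and reported.
* After phenotype QC or cohort/panel intersection, dosages are
  re-standardized on the analysis sample (standardization is
  affine-equivariant, so this equals standardizing the raw subset).
* The acceptance script's calibration study uses 2,000 null cohorts of
  n = 1,000 (one zero-effect SNP each) — large enough that the
  method-of-moments df estimate has Monte-Carlo SE ≈ 0.045 — and the
  coverage study in the test suite uses 200 cohorts of n = 5,000, sizes
  chosen to make the whole validation run comfortably on a single CPU.
* Wald coverage, null calibration (Kolmogorov–Smirnov against
  chi-squared(2)), the any-age type-I bound, and equivalence with both a
  reference Cox implementation and a derivative-free maximizer of an
  independently written partial likelihood are all asserted in
  `tests/test_acceptance.py`; the tests compute every number they check.

## Known limitations

* The linear trajectory is an extrapolation: far from the observed age
  range `beta(t)` and `chi2(t)` are model artifacts, which is exactly why
  the maximum-evidence test clamps to (45, 52).
* The slope test's df = 2 reference is conservative; its power against
  pure-slope alternatives is accordingly reduced.
* No left truncation, frailty, stratified baselines, or time-varying
  covariates beyond the `x*(t - t0)` construction.
* The ridge AFT offset shrinks uniformly; very sparse architectures are
  better served by supplying externally computed predictors.
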