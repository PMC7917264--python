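# Methods

## Model

For units i = 1..N, occasions t = 1..T, and variables j = 1..k, the GCLM is

```
x[i,t,j] = alpha[t,j] + lam[t,j] * eta[i,j]
         + sum_h beta[j,m,h,t] * x[i,t-h,m]        (AR for m=j, CL for m!=j)
         + sum_h delta[j,m,h,t] * u[i,t-h,m]       (MA for m=j, CLMA for m!=j)
         + u[i,t,j]
```

with unit effects `eta_i ~ N(0, psi_eta)` and impulses
`u_{i,t} ~ N(0, psi_u[t])` allowing contemporaneous co-movement across
variables. The first occasion is predetermined: lag-h coefficients exist for
`t = h+1 .. T` (configurable per coefficient via `occasion_overrides`).
Coefficients may be tied across occasions (time-invariant) or free at every
occasion (time-varying) per family.

### SEM form and implied moments

The latent vector stacks kT *observation analogs*, kT *impulses*, and the
unit effects; the measurement matrix picks out the analogs, and all dynamics
live in a strictly causal (nilpotent on the analog block) structural matrix
B. Implied moments follow as

```
mu    = Lambda (I - B)^-1 alpha
Sigma = Lambda (I - B)^-1 Psi (I - B)^-T Lambda^T
```

where Psi is block-diagonal with one impulse covariance per occasion and the
unit-effect covariance. Because all observed variability is carried by the
latents, the measurement residual is zero and the marginal law of the wide
observed vector is exactly `N(mu, Sigma)`.

## Identification

`count_free_parameters` itemizes free parameters under the spec's
tying/anchoring conventions and warns when a variable's own-equation dynamic
parameters exceed its `T(T-1)/2` auto-covariances, or when the total exceeds
all first and second moments. `fit_ml` refuses such specs with
`IdentificationError` unless `allow_underidentified=True`. Freely estimated
loadings combined with free unit-effect variances leave the latent scale
undetermined; `fit_ml` therefore anchors the first loading to 1
(`fix_first`) automatically. The fully time-varying two-variable, six-wave
spec is the canonical under-identified case that the shrinkage priors
rescue.

## Maximum likelihood

The complete-case likelihood depends on the data only through the sample
mean and covariance of the wide vector, so each evaluation costs O((kT)^3)
regardless of N. The objective is maximized by L-BFGS-B on a transformed
parameter vector in which each covariance block is parameterized by its
log-Cholesky factor (log diagonal, raw sub-diagonal), making every iterate's
Psi positive semi-definite by construction. Standard errors come from the
inverse observed information (central-difference Hessian) with the delta
method through the structural map; AIC/BIC use the complete-case N. A
slower pure-NumPy reference (`marginal_loglik`) cross-checks the compiled
kernel and also supports per-missingness-pattern marginal likelihoods.

## Bayesian estimation

### Priors

- Coefficients default to diffuse `N(0, 1e10)`.
- Small-variance ("null") priors `N(0, 0.01)` bet against specific terms
  (e.g. higher lags, unit-effect loadings), placing ~95% prior mass within
  ±0.196.
- **Difference priors** on a time-varying coefficient group are zero-mean
  MVNs with diagonal `d` (default 1000) and off-diagonal `d - v/2`, so that
  each pairwise difference has prior variance `v` (default 0.01: ~68% mass on
  differences within ±0.1) while the common level stays diffuse. The group
  covariance is positive definite whenever `d > v/2 > 0`.
- Covariance blocks carry weakly informative priors on the sampling scale:
  half-normal(10) on Cholesky diagonals (with the log-scale Jacobian) and
  `N(0, 100)` on off-diagonal Cholesky entries.

`bayes1_config` applies difference priors to all nine time-varying
coefficient families of the income/SWB spec plus a mean-stationarity
difference prior on the SWB loadings and null priors on the income
loadings; `bayes2_config` additionally nulls the second-order income MA
terms.

### Sampler

Laplace-preconditioned adaptive random-walk Metropolis, JIT-compiled:

1. posterior mode by L-BFGS-B; observed information by numerical Hessian;
2. proposal covariance = eigenvalue-floored inverse information scaled by
   `2.38/sqrt(d)` (flat/under-identified directions get wide proposals);
3. per-chain Robbins–Monro adaptation of a global log step size toward 0.234
   acceptance during burn-in only (preserving detailed balance afterwards);
4. two or more chains from jittered overdispersed starts, thinned before
   retention; all chain seeds descend from one `SeedSequence`.

### Diagnostics and fit indices

- **PSR** (Gelman–Rubin), conventional 1.05 cut-off.
- **Between-chain KS tests** with Bonferroni family-wise control at 0.05;
  because the KS test assumes independent samples, each chain is first
  subsampled at the lag where its autocorrelation drops below 0.1.
- **PPP** with a chi-square-style discrepancy
  `-2 [loglik(theta; Y) - saturated(Y)]`, comparing the observed panel with
  a same-size replicate simulated at each (subsampled) posterior draw; 0.5
  is ideal and values below 0.05 flag misfit.
- **DIC** = mean deviance + pD, pD = mean deviance − deviance at the
  posterior mean. pD is not an integer in general and shrinks under
  informative priors — the operational sense in which shrinkage priors
  reduce model dimension.

## Inference surface

- **Combined short-run effect** of a source on a target: the sum of the CL
  and CLMA coefficients at a given lag, either at one occasion or averaged
  across occasions. ML uses the delta method on the linear combination;
  Bayes sums per draw and reports HPD intervals.
- **Granger-style comparison** fits four models — full, each direction of
  cross-effects removed, and both removed — on the same data, seeds, and
  settings, and reports criterion differences (AIC/BIC for ML, DIC for
  Bayes) rather than p-values.
- **Impulse responses** iterate the structural recursion on the fitted
  coefficients: horizon h uses occasion `t0 + h`'s coefficients; beyond T
  the last occasion's coefficients persist with a warning (exact for
  time-invariant models); an `averaged` mode uses across-occasion means.
  `r[1]` equals the combined short-run effect by construction. Bands come
  from per-draw IRFs with HPD intervals (Bayes) or parametric draws from the
  estimator's asymptotic normal (ML).

## Synthetic data generator

`income_swb_preset()` encodes the structure of a published national income /
subjective-well-being panel: near-unit-root income (AR 0.97 with negative
MA), moderately persistent well-being (AR 0.34), a positive income→SWB
cross-lagged path (0.24) with near-zero reverse path, strongly correlated
unit effects, and occasion-specific impulse co-movement. Impulse variances
are set to 1 because raw scales are not published; loadings are fixed at 1
to keep the preset ML-identifiable. These presets are study conditions, not
tuning knobs. Initialization is either predetermined (first occasion drawn
from its own marginal) or stationary burn-in (requires time-invariant
coefficients, occasion-constant impulse covariance, and companion-matrix
spectral radius < 1).

## Numerical design

- One slot/parameter enumeration (`enumerate_slots`) is the single source of
  truth for parameter order and naming across ML, MCMC, and reporting.
- Likelihood, log posterior, and the Metropolis loop are numba-jitted and
  operate on flat index arrays; ~50–60 µs per likelihood evaluation for the
  k=2, T=6 model, independent of N.
- Invalid regions (overflowing transforms, non-PD implied covariances)
  return −1e300 rather than raising, so optimizer and sampler treat them as
  ordinary rejections.
- Seeds: every public entry point takes an explicit seed; chain seeds and
  replicate seeds are derived through `numpy.random.SeedSequence`.
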