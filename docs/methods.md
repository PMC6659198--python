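# Methods

## Model

One likelihood couples two sub-models through shared subject-level random
effects `u_i = (u_i0, u_i1) ~ N(0, D)`:

* **Longitudinal**: `y_ij = m_i(t_ij) + eps_ij`, with the error-free
  trajectory `m_i(t) = x_i(t)' beta + u_i0 + u_i1 t` linear in time, fixed
  effects for time, arm, arm-by-time, baseline MMSE and site, and
  `eps ~ N(0, sigma^2)` independent of `u_i`.
* **Survival**: proportional hazards
  `lambda_i(t) = lambda_0(t) exp{gamma' w_i + assoc_i(t)}` with time-fixed
  covariates `w_i` (arm, optionally baseline MMSE, site) and an association
  term that injects the trajectory: its current value (`alpha1 m_i(t)`),
  value plus slope (`+ alpha2 m_i'(t)`), or cumulative value
  (`alpha3 * integral of m_i` up to `t`).

The per-subject likelihood contribution integrates the product of the
longitudinal normal density, the event-time density
`lambda_i(T)^delta exp(-Lambda_i(T))` and the `N(0, D)` density over `u_i`.
Censoring is assumed right-censoring, non-informative given covariates and
random effects. All times are years since randomization.

Under the current-value association the arm hazard ratio between otherwise
identical subjects is `exp{gamma1 + alpha1(beta2 + beta3 t)}`; the package
reports it as the product of the direct (`exp(gamma1)`), indirect-constant
(`exp(alpha1 beta2)`) and indirect-time-varying (`exp(alpha1 beta3 t)`)
components. This multiplicative identity holds exactly by construction and is
asserted to 1e-12 in the tests. The decomposition is a description of the
fitted hazard ratio, not a formal causal-mediation estimand.

## Estimation

* **Baseline hazard**: piecewise constant on `Q` intervals (default 7),
  interior knots at equally spaced quantiles of the observed event times;
  intervals without events are merged into their left neighbour; intervals
  are half-open `[k_{q-1}, k_q)`, so an event on a knot belongs to the right
  interval. A parametric baseline makes the full joint likelihood a smooth
  finite-dimensional object that a quasi-Newton optimizer can maximize
  directly.
* **Random-effects integral**: pseudo-adaptive Gauss-Hermite quadrature.
  Each subject's node grid is centred and scaled by their longitudinal-only
  posterior of `u_i` (available in closed form given the mixed-model
  parameters), then held fixed during optimization. 15 points per dimension
  is the default; at the optimum of a default-size trial, moving from 15 to
  25 points changes the total log-likelihood by less than 1e-3 (a tested
  invariant), and 7-9 points give estimates indistinguishable to ~0.01, which
  is why the simulation studies in the test suite use 9 points and 4-5
  baseline intervals.
* **Cumulative hazard**: on each baseline interval the integrand is
  `lambda_q exp(a + c s)` for the value and value+slope structures and is
  integrated in closed form, with a series expansion of
  `(e^{c t2} - e^{c t1})/c` (and its `c`-derivative) below `|c| t < 1e-3` to
  avoid cancellation; for the AUC structure the integrand is
  `lambda_q exp(quadratic in s)` and fixed-order Gauss-Legendre (default 15
  nodes) is applied per interval.
* **Optimization**: direct BFGS maximization of the total log-likelihood over
  all parameters simultaneously, on a transformed scale that enforces the
  constraints automatically - log-Cholesky factor of `D`, `log sigma`, log
  baseline-hazard levels. Gradients are analytic (derived by hand for every
  parameter block) and verified against central finite differences in the
  test suite; this is what makes the bootstrap and the replicated simulation
  studies affordable. Initial values come from the longitudinal-only ML fit
  and the covariates-only piecewise-exponential fit, with association
  coefficients started at zero.
* **Uncertainty**: observed information obtained by central finite
  differences of the analytic gradient at the optimum; the covariance matrix
  is mapped to the reporting scale (beta, D entries, sigma, log-baseline
  levels, gamma, alpha) by the delta method, and Wald two-sided p-values use
  a standard-normal reference. AIC/BIC use the number of free parameters and
  (for BIC) the number of subjects.
* **Longitudinal-only fit**: ML, not REML, so its estimates live on the same
  likelihood scale that initializes the joint fit. The fixed effects are
  profiled out and the four variance parameters optimized by BFGS.
  Baseline MMSE is mean-centred before entering any design matrix, which
  keeps the intercept interpretable and the optimization well scaled; site
  enters both sub-models as reference-coded contrasts (first level sorted
  lexicographically is the reference).
* **Empirical Bayes**: per-subject posterior modes of `u_i` given all data
  are computed on request by a 2-D Nelder-Mead refinement started at the
  longitudinal-only posterior mean.

## Bootstrap

Percentile bands for the total intervention hazard ratio use a cluster
bootstrap: whole subjects (covariates, all longitudinal rows, survival row)
are resampled with replacement, the joint model is refitted per replicate
warm-started at the full-data estimates, and pointwise 2.5/97.5 percentiles
are taken over the replicate HR curves. Replicates that fail to converge are
dropped and counted; more than 20% failures raises an error. Everything is
driven by one seeded generator, so bands are reproducible given the seed.
The default grid is 0-2 years with 101 points. The tests run 200 replicates;
larger counts only tighten the band percentiles.

## Trial simulator

The generator emulates the study conditions the analysis is designed for:
311 subjects by default, 1:1 allocation, three sites, visits at 0/0.5/1/2
years with the post-baseline visits jittered by `N(0, 0.08^2)` years
(truncated at 0; the baseline visit stays at the randomization time, since
jittering it past an early event would delete the subject's entire
longitudinal record), administrative censoring at 2 years, and an
independent exponential dropout hazard of 0.05/year. Event times are drawn
exactly by inverting the subject-specific cumulative hazard
(`Lambda_i(T) = -log U`) with Brent root-finding against the same
closed-form/quadrature cumulative hazard used by the likelihood - a
brute-force grid-inversion oracle cross-checks this in the tests. Events
beyond 50 years are treated as never observed.

The default truth approximates the fitted regime the package targets: outcome
worsening 0.6/year, intervention slowing it by 0.23/year, association 0.66
per unit of current value, baseline-MMSE log-hazard effect -0.23, direct
effect 0.125, random-effect covariance diag(1.0, 0.25) with 0.1 covariance,
residual s.d. 0.5. The MMSE-like covariate is drawn on its raw ~0-30 scale
(mean 26.4, s.d. 2.0) and mean-centred before entering either model. The
constant true baseline hazard was calibrated once (log lambda0 = -3.35) so
that ~38% of subjects are diagnosed within the 2-year window, matching the
event fraction such trials report; the value+slope regime uses alpha_slope =
3.0 (a deliberately substantial slope association, in line with fitted slope
coefficients several times larger) and log lambda0 = -4.4, and the AUC regime
alpha3 = 0.4 with log lambda0 = -2.7, keeping event fractions near 0.3-0.45.
`confounded_variant` lowers the test arm's MMSE mean by 0.8 points (a gap a
two-sample t-test detects with ~94% power at n=311) while keeping the MMSE
hazard effect non-zero, so the arm is marginally associated with the hazard
at baseline - the confounding mechanism under study.

Three sites are simulated rather than the eleven of a typical multi-country
trial: with ~28 subjects per site, twenty reference-coded site contrasts
would be pure noise at this sample size, and the site-adjustment machinery is
exercised identically with two contrasts per sub-model.

What the simulator does **not** emulate: interval censoring of diagnosis
times (diagnoses cluster at visits in real trials; the fitted model assumes
right-censoring, so the simulator generates what the model fits),
missing-not-at-random visit processes, site-level random effects, competing
risks, floor/ceiling effects of bounded scales, and any measurement model
for MMSE itself. Passing tests therefore demonstrate correctness of the
estimator under its own assumptions, not robustness to these violations.

## Numerical choices and degenerate inputs

* Non-positive-definite `D` or non-positive `sigma` are rejected at
  construction; the log-Cholesky/log transforms keep the optimizer inside the
  valid region.
* Non-finite likelihood evaluations (overflow at extreme trial points)
  return `-inf` with a zero gradient, which the BFGS line search backtracks
  from.
* A fit is flagged converged when the optimizer reports success or the
  gradient infinity-norm falls below 1e-3; a singular observed information
  leaves the covariance absent and the fit flagged.
* Exactly one association configuration may be active; requesting a
  decomposition from a slope or AUC fit raises, since the multiplicative
  direct/indirect factorization is defined for the current-value structure.
* Re-fitting from a returned optimum changes the log-likelihood by < 1e-6
  (tested fixed point).

## Test-suite problem sizes

The simulation studies use sizes chosen to give stable Monte-Carlo margins:
parameter recovery runs 50 trials at n=311 (each key parameter within 3
reported s.e. of truth in >= 90% of replicates), confounding absorption 25
confounded trials, association selection 25 trials at n=250, and the
bootstrap-reproducibility check 200 replicates at n=120. The per-subject
likelihood is validated against plain Monte-Carlo integration with 1e6
normal draws (3 MC s.e.) and the longitudinal marginal against direct
multivariate-normal densities; statsmodels (MixedLM, Poisson GLM) serves as
an independent cross-check for the sub-model fits, never as the
implementation.
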