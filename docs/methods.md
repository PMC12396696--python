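# Methods

## Model

Knee flexion angles `y_ijt` (degrees) are observed for participant
`i = 1..n_j` in feedback group `j = 1..G` at stride steps `t = 1..T`
(`tau_t = t`, unit spacing; all derivatives below are therefore in
degrees/step).  The response model treats the group mean as a latent state,

    y_ijt = m_jt + eps_ijt,   eps_ijt ~ N(0, sigma2_jt),

and the state model couples consecutive angles through a retention factor A
and a learning rate B,

    y_ij,t+1 = A_j(tau_t) y_ijt + B_j(tau_t) m_jt.

Perturbations of the same participant are serially dependent; this is
absorbed by a stochastic log-variance transition

    log sigma2_jt = a_j log sigma2_j,t-1 + u_jt,   u_jt ~ N(0, sigma_u2),

with `a_j = 1`, `sigma_u2 = 0.01` and `sigma2_j0 = 1` by default.

## Sequential track

**Priors.** `m_jt ~ N(A_mjt, B_mjt^2)` with vague defaults (0, 10);
`sigma2_j1 ~ Inv-Gamma(A_sj, B_sj)` with defaults (2, 1); later variances
evolve by the transition, not a prior.

**Full conditionals.** `m_jt | . ~ N(M_jt, V_jt)` with
`V_jt = (n_j/sigma2_jt + 1/B_mjt^2)^-1` and
`M_jt = (sum_i y_ijt/sigma2_jt + A_mjt/B_mjt^2) V_jt`;
`sigma2_j1 | . ~ Inv-Gamma(n_j/2 + A_sj, 0.5 sum_i (y_ij1 - m_j1)^2 + B_sj)`.

**Filter.** Each particle carries the variance vector
`(sigma2_1t, ..., sigma2_Gt)`.  Per step: propagate the log-AR(1)
transition; draw `m_jt` per particle from its Normal full conditional
(conditional on that particle's variances — one Gibbs sweep, no inner
iterations); multiply the importance weight by the step's response
likelihood (all weight arithmetic in the log domain, so 500-step products
cannot underflow); then control the population.  Control: a particle whose
weight exceeds `theta_high = 5 W/N` (W total weight, N population size) is
split into `ceil(w/theta_high)` equal-weight copies (total weight conserved
exactly); a particle below `theta_low = 0.2 W/N` survives with probability
`w/theta_low` at weight `theta_low` (conserved in expectation).  Population
bounds default to [1000, 10000] and are enforced by limiting splits and by
force-keeping the heaviest would-be-pruned particles at their original
weight.  Point estimates are simple (unweighted) particle means; 95% bands
are the 2.5/97.5 unweighted particle percentiles — consistent with using
the simple mean, which is justified because the weight control keeps all
weights within a factor ~25 of the average.  Default 5000 particles.

**Constant rates.** `A_j`, `B_j` solve the no-intercept Gaussian regression
`response_t+1 = A_j response_t + B_j driver_jt + e` with group-specific
residual variances; the driver is the particle-filter mean series, the
sample mean series, or a user-supplied series.  The fit is exact ML:
closed-form weighted least squares given the variances, iterated with ML
variance updates to a 1e-10 tolerance on log variances — deterministic, no
stochastic optimizer.  Standard errors come from the coefficient block of
the observed information at the optimum.  The fit is computed at the
individual level (all participants' transitions stacked per group) by
default; the group-mean level is also exposed but is rank-deficient when
the driver *is* the group mean (lag and driver identical), which the code
rejects with a named-group error.  Group equality of A (or B) is tested by
the chi-squared difference of the `-2 log L` of nested fits (coefficient
shared across groups vs free), df = G - 1 constraints; the absolute
model-vs-saturated chi-squared of SEM software is not reproduced, only the
difference, which is what carries the inference.

## Functional track

The group mean is expanded as `m_jt = f_j(tau_t) + delta_jt`,
`delta_jt ~ N(0, sigma2_jd)`, `eps_ijt ~ N(0, sigma2_e)`, with `f_j` a cubic
truncated-power P-spline: basis row
`x_t = [1, t, t^2, t^3, (t - mu_1)+^3, ..., (t - mu_K)+^3]`, `K = 19`
equally spaced knots (25, 50, ..., 475 for T = 500), and diagonal penalty D
with zeros on the four polynomial coefficients and ones on the knot
coefficients, so only local deviations from a global cubic are shrunk.
Priors: `beta_j ~ N(0, (alpha*_j D)^-)`, `alpha*_j ~ Gamma(A_t, B_t)`,
`sigma2_jd ~ Inv-Gamma(A_d, B_d)`, `sigma2_e ~ Inv-Gamma(A_e, B_e)`; all six
hyperparameters default to 0.01 (vague) and are configurable.

Gibbs blocks, cycled in fixed order (beta_j, m_j, alpha*_j, sigma2_jd per
group, then sigma2_e):

* `beta_j ~ N((X'X + alpha_j D)^-1 X'm_j, (X'X + alpha_j D)^-1 sigma2_jd)`
  with `alpha_j = alpha*_j sigma2_jd` — the only scaling under which this
  conditional, the `alpha*` prior and the model are mutually consistent;
* `m_jt ~ N(p^-1 (sum_i y_ijt / sigma2_e + f_jt / sigma2_jd), p^-1)` with
  precision `p = n_j/sigma2_e + 1/sigma2_jd` — the standard conjugate
  combination of the participant data and the spline fit;
* `alpha*_j ~ Gamma(A_t + rank(D)/2, B_t + 0.5 beta_j' D beta_j)`;
* `sigma2_jd ~ Inv-Gamma(A_d + T/2, B_d + 0.5 ||m_j - X beta_j||^2)`;
* `sigma2_e ~ Inv-Gamma(A_e + T sum_j n_j / 2, B_e + 0.5 sum residual^2)`.

All five blocks are validated jointly by a getting-it-right check (below).
Default chain sizes: 1000 retained draws after 1000 burn-in, seeded.

Per draw `s`, curves are `f^(s) = X beta^(s)` and derivatives are unit-step
first differences `f'^(s)(tau_t) = f^(s)(tau_t+1) - f^(s)(tau_t)`.  The
time-varying rates are

    A_j(tau_t) = f_j'(tau_t),
    B_j(tau_t) = (ybar_j,t+1 - f_j'(tau_t)) / f_j(tau_t),

with bands from the 2.5/50/97.5 across-draw percentiles of the same
transforms; point estimates use the across-draw mean curve and derivative.
For a single draw the reconstruction `ybar_j,t+1 = A + B f` is an algebraic
identity, which the tests verify to machine precision.  Note the scales:
this A is a derivative (degrees/step) near zero away from the phase jump,
whereas the sequential track's A is a dimensionless multiplier near one;
the two are related only loosely (an `A(tau) - 1` reading), and the package
reports both without enforcing a numeric bridge.  Because B divides by the
curve, a floor `|f| >= 1e-6` guards the transform; baseline-adjusted data
(near-zero means) will trigger the guard and flag B unavailable with a
warning — the rate functions are intended for raw angles.

Band overlap: for each group pair, parameter and step, the bands are
flagged *disjoint* when one interval lies strictly above the other;
contiguous disjoint runs are summarized.  These flags are descriptive —
the B bands propagate curve uncertainty but not the sampling noise of the
observed means in the numerator, so isolated disjoint cells occur even
between identically generated groups; inference should read concentrated
runs, not single steps.

## Synthetic cohorts

`generate_cohort` emulates the study design: G = 3 groups (Control,
Punishment, Reward) x 11 participants x 500 steps, baseline 60 degrees for
steps 1-250, +30 degree target from step 251.  The latent group mean
follows `m_j,t+1 = A_j m_jt + B_j d_jt` where the driver `d_jt` is the phase
target rescaled by `(1 - A_j)/B_j`, so the recursion's fixed point equals
the target; observations add a constant participant offset
(SD 3 degrees by default, reflecting the individual scatter of real
kinematics; set to 0 for pure-model tests) and Gaussian noise with the
log-AR(1) variance path.  Default (A_j, B_j) are study-like values:
(0.9404, 0.0477), (0.9394, 0.0567), (0.8889, 0.1231).  The generator
returns the full ground truth (latent means, realized means including the
average offset, variance paths, driver, offsets) and supports a
baseline-adjusted convention and explicit variance profiles (e.g. a
variance jump at the phase change).

What the generator does **not** emulate: serial correlation of a
participant's noise beyond the shared variance path, gait biomechanics,
feedback-score dynamics, drop-outs or missing steps.  Passing tests on
these cohorts therefore demonstrate correctness of the estimators under the
model's own assumptions, not robustness to every feature of real
recordings.

`simulate_state_model_cohort` generates instead directly from the
individual-level state regression (`y_t+1 = A y_t + B d_t + e`, iid errors).
This is the calibration oracle: under it the constant-rate fit is exactly
the true model, so likelihood-ratio statistics follow their nominal
chi-squared null and model-based standard errors match sampling variation.

## Validation designs

* **Conjugate oracle.** With the variance frozen at truth and no
  propagation noise, the filter's mean track must match the closed-form
  Normal posterior mean step by step (<0.5% relative error at 5000
  particles).
* **Getting-it-right.** The five FDA conditionals are checked on a T = 60,
  K = 4 miniature with a full-rank penalty (the default rank-K penalty
  implies an improper prior on the cubic, which cannot be simulated) and an
  O(1) time grid (at raw step scale the prior curve distribution is so
  heavy-tailed that no finite-sample summary is usable).  Two thousand
  independent chains are initialized with exact prior draws and advanced 10
  sweeps with data re-draws; if every conditional is correct the final
  states are exact prior draws, so two-sample Kolmogorov-Smirnov tests
  against direct prior simulation (one per block, 1% level) are valid
  without any mixing assumptions.  The design detects an injected
  off-by-one in the `sigma2_jd` shape at p ~ 1e-7.
* **Recovery.** Regressing noisy observations on their own lag attenuates A
  (errors in variables): the raw individual-level fit under-estimates A by
  ~0.14 at the default noise level.  Recovery of the generative rates is
  therefore assessed with the group-level fit on smoothed series (window-9
  centered moving average applied identically to response, lag and driver
  — a linear filter under which the recursion is exactly preserved while
  the regressor noise drops ~9-fold); measured bias is < 0.002.  The
  table-style fits deliberately keep the raw series, matching how the
  estimators are used on data.
* **Coverage.** Particle-band coverage of the latent mean is evaluated on
  pure-model cohorts (offsets 0), because a constant participant offset is
  observationally equivalent to a shift of the group mean and inflates
  nominal coverage.  P-spline band coverage is evaluated on cohorts drawn
  from the spline hierarchy itself with a known smooth (logistic-shaped)
  mean, since no spline band can cover a discontinuous latent mean at the
  jump step.  Both run 100 replicates at full study size.

## Numerical choices

* Particle weights live in the log domain end to end; per-step
  normalization keeps them bounded and the pre-normalization total is
  recorded as a log-evidence increment diagnostic.
* The spline design matrix is column-scaled internally before the Cholesky
  solves (raw truncated-power columns at t up to 500 span ~8 orders of
  magnitude); draws are mapped back exactly, so the posterior is unchanged.
* ML iteration tolerance 1e-10 on log residual variances, cap 500
  iterations; residual variances floored at 1e-300 so noiseless fixtures
  stay finite.
* Rank checks use the SVD with a 1e-10 relative singular-value threshold;
  rank-deficient groups/participants are reported by name, and per-
  participant failures do not abort the remaining fits.
* Negative chi-squared differences beyond -1e-6 (relative) raise; smaller
  numerical negatives clamp to zero.
* Reading CSVs uses round-trip float parsing and writing uses 17
  significant digits, so write -> read is bit-exact.

## Problem sizes in the shipped checks

The test suite and the acceptance script run at the full study design
(T = 500, 3 x 11 participants) for single-cohort analyses, 5000 particles
for headline filter runs and 1000 particles for replicate studies, 100
replicates for recovery/coverage, 300-500 replicates for null calibration,
and 300-1000 retained MCMC draws depending on whether the quantity needs
tail quantiles.  These sizes were chosen so each Monte-Carlo check has
standard error comfortably below the tolerance it asserts.

## Limitations

* The constant-rate regression on raw observed series estimates a linear
  projection, not the generative (A, B), whenever observation noise sits on
  the lagged regressor; group *comparisons* remain meaningful because all
  groups share the same attenuation, but absolute values should be read
  with this in mind (the smoothed-fit recovery estimator quantifies the
  gap).
* Equality chi-squared tests inherit the regression's iid-error assumption;
  under strong within-participant correlation (e.g. large constant offsets)
  the statistics are anti-conservative.
* The filter performs no backward smoothing and does not learn `a_j` or
  `sigma_u2`; the spline track uses fixed, equally spaced knots and a
  single global error variance.
* The weight-control thresholds and population bounds are sensible defaults
  validated by conservation tests, not tuned optima.
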