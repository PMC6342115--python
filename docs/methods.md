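# Methods

## Model

`prefsdm` fits species distribution models in which the choice of sampling
locations may depend on the abundance surface being measured — the
*preferential sampling* problem.  The data are read as a marked point
pattern: the sampling locations form a point pattern, and the abundance
measured at each location is its mark.

The joint (preferential) model has two coupled layers sharing one latent
Gaussian field W with Matérn covariance:

* **Mark layer.**  Marks follow an exponential-family distribution; the
  default is a gamma with mean mu and shape rho,

      y_i ~ Ga(mu_i, rho),    log mu_i = b' + W(s_i) [+ f(d_i)],

  where f(d) is an optional second-order random-walk (RW2) smooth over a
  binned covariate such as bathymetry.  Gaussian (identity link),
  lognormal and Poisson mark families are also available.

* **Point-pattern layer.**  Sampling locations are a log-Gaussian Cox
  process whose log-intensity shares the same field, rescaled by a
  *sharing coefficient* alpha that absorbs the difference in scale
  between intensities and abundances:

      Lambda(s) = exp( b0 + alpha * W(s) [+ alpha_d * f(d(s))] ).

  On the analysis grid the LGCP likelihood is approximated by
  independent Poisson counts per cell with the cell area as exposure.
  This lattice approximation — rather than a dual-mesh scheme — is the
  key numerical-fidelity decision: the data grid is already a lattice,
  so the count approximation is exact at the resolution the model sees.

The non-preferential baseline is the mark layer alone; it corresponds to
giving the point pattern its own independent field, which then carries no
information about the marks.

When alpha > 0, cells without points are (weak) evidence of low W, which
is what corrects the upward bias that a mark-only model suffers under
preferential sampling.

## Latent field

The Matérn smoothness is fixed at nu = 1 (the SPDE operator power
alpha_SPDE = 2).  The range convention is

    range = sqrt(8 * nu) / kappa,

the distance at which correlation has decayed to roughly 0.1 (the exact
nu=1 value at one range is sqrt(8) K1(sqrt(8)) = 0.1397).  The marginal
variance obeys sigma^2 = 1 / (4 pi kappa^2 tau^2).  This convention is
stated prominently because different software stacks differ here.

The precision matrix is the lattice SPDE discretization
Q = (tau/h)^2 (kappa^2 h^2 I + L)^2 with L the 4-neighbour graph
Laplacian — a 13-point stencil, at most 13 nonzeros per row.  Natural
(Neumann) boundaries inflate the variance near the edge, so Q is always
built on the grid extended by one correlation range on every side
(configurable) and the study window is recovered by selection.  In the
fitter the latent vector simply lives on the extended grid; the default
model padding is 20% of the longer grid side, matching the default
generator range, because the latent dimension must stay fixed while the
posterior range varies.

Simulation uses the exact dense Matérn Cholesky for grids up to 64x64
(enabling exact-covariance testing) and otherwise one sparse solve of
white noise through the square-root operator (tau/h)(kappa^2 h^2 I + L),
which has precision exactly Q.  The path taken is recorded in the field
metadata.

## Inference

Fitting is *empirical-Bayes Laplace*, a deliberately reduced version of
the nested-Laplace (INLA) scheme:

1. **Inner loop.**  Newton optimization of the joint negative log
   posterior over the latent vector (field, intercepts, smooth) at fixed
   hyperparameters.  Both likelihood layers have log-concave terms, so
   the Hessian is positive definite by construction; factorizations use
   a sparse LU with symmetric minimum-degree permutation and diagonal
   pivoting (which certifies positive definiteness and yields the log
   determinant).  Tolerance 1e-8 on the gradient max-norm, at most 50
   iterations, step-halving (Armijo) line search.  A step whose
   predicted decrease falls below the floating-point noise floor is
   treated as converged.

2. **Outer loop.**  The Laplace-approximated log marginal posterior of
   the hyperparameters — (2 log kappa, log tau), log dispersion, alpha,
   and optionally (log rho_d, alpha_d) — is maximized by Nelder–Mead
   from deterministic initials: range at half the window, prior-median
   sd, method-of-moments dispersion, alpha = 1, W = 0, intercepts at the
   link-transformed mark mean.  The field-prior log determinant uses the
   closed-form lattice spectrum (the Neumann path-graph Laplacian has
   eigenvalues 2(1 - cos(pi k / n))), so each outer evaluation costs one
   or two sparse factorizations.

3. **Summaries.**  Latent marginal standard deviations come from the
   Gaussian approximation at the hyperparameter mode (sparse multi-RHS
   solves; no dense inverse is formed).  Hyperparameter standard errors
   come from a finite-difference Hessian of the outer objective;
   an optional coarse 3^p grid around the mode gives weighted
   posterior-mean summaries (`integrate_grid=True`).  Full CCD
   exploration and the simplified/full Laplace marginal corrections of
   complete INLA are out of scope.

Priors: vague zero-mean Gaussians with variance 100 on the intercepts;
on (2 log kappa, log tau) either independent Gaussians whose medians put
the prior-median range at half the window and the prior-median sd at 1
(sd sqrt(10) on each coordinate), or penalized-complexity priors
specified as P(range < r0) = p_r and P(sd > s0) = p_s; N(0,1) on alpha
(natural scale) and on alpha_d; N(0, 10^2) on the log dispersion;
LogGamma(4, 1e-4) on the RW2 precision rho_d.  The choices for alpha and
the dispersion are this package's own — the literature the model follows
leaves them unstated.

The RW2 structure matrix is scaled so the geometric mean of its
generalized marginal variances is 1; its level and slope null space is
made proper by giving those two components the same vague Gaussian prior
as the fixed effects (a soft sum-to-zero/no-trend constraint).

When both the smooth and the field are shared into the point-process
layer, the two sharing scales can carry nearly the same information; the
fitter detects this (near-singular outer curvature or |corr| > 0.95
between alpha and alpha_d) and reports `shared_confounding` in the
diagnostics rather than failing silently.  The option is flagged
experimental.

## Scoring

All scores are computed on the **mark likelihood only**, so the joint
model and the mark-only baseline are directly comparable; lower is
better.

* **DIC** = Dbar + pD with Dbar the posterior-mean deviance of the mark
  linear predictor under the Gaussian approximation at the hyperparameter
  mode, and pD = Dbar − D(posterior mean).  For every built-in family
  that expectation has a closed form in the marginal moments of eta (it
  needs only E[eta] and E[e^{-eta}] or E[e^{eta}]), so the default is the
  exact infinite-draw limit; a seeded Monte-Carlo path (default 1000
  draws) remains for posterior objects that only expose a sampler.
  Because both models are scored on the mark likelihood at their own
  empirical-Bayes dispersion mode, DIC separates the two models less
  sharply than LCPO or MAE in the shipped study: a mark-only baseline
  can lower its mean deviance by inflating its dispersion estimate, and
  pD evaluated at that same inflated mode only partly pays for it.
* **LCPO** = −(1/n) Σ log CPO_i.  The approximate route deflates each
  observation's full-data Gaussian marginal by its local quadratic
  likelihood contribution and integrates the 1-D predictive by
  Gauss–Hermite quadrature (41 nodes, deterministic); the plain
  harmonic-mean identity is not used because its expectation diverges
  for log-link gamma tails.  The `exact_loo` route re-optimizes the
  latent field with the mark term removed — hyperparameters held at the
  full-data mode — which keeps n refits desk-feasible and isolates the
  deflation approximation; dropping a mark keeps its location in the
  point pattern.
* **MAE** is the mean absolute difference between the posterior
  predictive mean surface and the true mean-abundance surface
  exp(intercept + W_true) over **all** grid cells (simulation truth is
  known); a held-out-points variant is available.  The predictive mean
  uses the lognormal correction E[exp(eta)] = exp(m + v/2), not
  exp(E[eta]).

## Synthetic scenarios

`make_scenario` emulates the reference simulation design: a zero-mean
Matérn field on a 100x100 grid, two samples of n=100 locations each —
one uniform, one with cell probabilities proportional to exp(b W)
(log-sum-exp normalized), b=1 by default — and marks extracted at the
sampled cells.  Sampling is with replacement at the cell level (100 of
10,000 cells; a flag disables replacement).  Marks default to the gamma
family with shape rho=10 and intercept 0 on the log scale, matching the
analysis likelihood; the generating field parameters (sigma^2 = 1, range
= 20% of the window width) are this package's choices, as the reference
experiment does not state its values, and whether the extracted
"abundance estimates" carried observation noise is likewise unstated —
both gamma-noise and gaussian-noise extraction are implemented, with the
gamma default documented here rather than asserted as the original
design.  Sub-seeds are split from the master seed as
`SeedSequence(master, spawn_key=(stage,))`, so every stage is
independently reproducible.

What the generator does *not* emulate: covariate-driven trends,
anisotropy or non-stationarity, detection effort, off-grid (continuous)
locations, and temporal structure.  Passing tests therefore demonstrate
correctness of the preferential correction under a clean shared-field
data-generating process, not robustness to misspecification in real
surveys.

## Study scale

The shipped simulation study defaults to 30 replicates on a 32x32 grid
with n=100 and b=1 — a size chosen so the full 2-designs x 2-models
comparison finishes in minutes on one CPU while keeping ~25 independent
field patches per replicate.  `StudyConfig.paper_scale()` gives the full
100-replicate, 100x100 configuration, which is long-running.  Failed
fits are logged, excluded from summary fractions, and counted in the
report.

## Numerical notes and limitations

* Hyperparameter uncertainty is Gaussian on the internal scale
  (2 log kappa, log tau, log dispersion, alpha); equal-tailed intervals
  are therefore symmetric on that scale.
* Duplicate sampled cells contribute independent mark terms and count-2
  cells in the pattern term.
* Degenerate inputs: empty samples, non-positive gamma marks,
  out-of-window locations, non-finite fields and invalid hyperparameters
  all raise `ArgumentError` before any optimization starts; inner
  non-convergence raises `ConvergenceError` carrying diagnostics.
* The LGCP cell-count approximation limits intensity resolution to the
  grid; sub-cell clustering is invisible.
* Empirical-Bayes scoring ignores hyperparameter uncertainty in DIC,
  LCPO and the predictive surfaces; the optional grid integration
  affects only reported hyperparameter summaries.
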