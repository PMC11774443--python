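# Methods

## Model

The package models multi-trial neural recordings with a continuous-time
latent SDE

    dx = ( f(x) + B v_t ) dt + Sigma^{1/2} dw,        x in R^K,

observed either as per-channel Poisson processes with intensity
`lambda_d(t) = exp(c_d^T x(t) + d_d)` (spike trains) or as Gaussian samples
`y_i ~ N(C x(t_i) + d, R)` on a time grid (imaging traces).  `v_t` is an
optional known input signal entering additively through `B`.

Each drift component `f_k` carries an independent zero-mean GP prior with the
**smoothly switching linear (SSL) kernel**

    k(x, x') = sum_{j=1..J} [ (x - c_j)^T M (x' - c_j) + sigma0^2 ]
               * pi_j(x) pi_j(x'),

    pi_j(x) = softmax_j( w_j^T phi(x) / tau ),   w_J = 0.

The first factor is a linear kernel per regime (GP samples are affine with
slope variance `M = diag(M_diag)` and minimum variance `sigma0^2` at the
center `c_j`); the second is a partition kernel built from a
temperature-controlled multiclass logistic regression over regimes.  Samples
are therefore locally linear flow fields that interpolate smoothly across the
decision boundaries `w_j^T phi(x) = 0`.  As `tau -> 0` the partition hardens
to piecewise-constant switching; as `tau -> infinity` it flattens to `1/J`.
`phi` is the affine feature map `(x, 1)` by default; the `quadratic` map adds
pairwise products, making curved boundaries (circles, parabolas) linear in
feature space.  `M` and `sigma0^2` are shared across regimes.  An RBF kernel
is available behind the same interface as the unstructured baseline.

## Inference

The posterior is approximated by the factorization
`q(x) prod_k p(f_k | u_k) q(u_k)` with inducing values `u_k = f_k(Z)` at `M`
fixed locations `Z` (a regular grid over the initialized latent range).

**Path posterior q(x).**  Per trial, `q(x)` is the law of a linear
time-varying SDE `dx = (A(t) x + b(t)) dt + Sigma^{1/2} dw` from
`N(m_0, S_0)`.  Its marginals obey the forward moment equations
`m' = A m + b`, `S' = A S + S A^T + Sigma`, discretized with forward Euler on
a uniform inference grid (default 5 ms).  The evidence lower bound is

    ELBO = sum_trials [ E_q log p(y | x)  -  integral e(t) dt  -  KL_0 ]
           - sum_k KL( q(u_k) || N(0, K_zz) ),

    e(t) = 1/2 E_q[ (f(x) + B v - A x - b)^T Sigma^{-1} (...) ],

where the drift moments under `q(f|u) q(u) q(x_t)` require Gaussian
expectations of kernel evaluations (psi statistics), computed by
tensor-product Gauss-Hermite quadrature after a Cholesky transform of each
marginal covariance.  The controls are updated by a forward-backward sweep:
Lagrange multipliers `(lambda, Psi)` for the moment constraints are integrated
backward with jumps from the observation terms, giving the stationarity
proposals

    A*(t) = E_q[df/dx](t) + 2 Sigma Psi(t+),
    b*(t) = E_q[f + Bv](t) - A*(t) m(t) + Sigma lambda(t+),
    m_0*  = mu_0 + V_0 lambda(0),    S_0* = (V_0^{-1} - 2 Psi(0))^{-1}.

The recursions are derived from the discrete-time Lagrangian of the
Euler-discretized problem, so the update and the objective are consistent at
the grid level; the linear-Gaussian special case reproduces a discretized
Kalman smoother to < 1e-3 at a 1 ms grid (verified in the tests).
Proposals are blended with the current controls and accepted only if the
trial's ELBO contribution does not decrease, halving the blending factor
otherwise (initial 0.5, floor 1e-7); the controls and the initial condition
are accepted in separate stages because the multiplier-based initial-state
proposal can overshoot far from the optimum.  This makes every path update
monotone by construction.

Gradients of `e(t)` with respect to `(m, S)` differentiate the quadrature
rule itself (kernel input-gradients at the nodes, plus the standard
Cholesky backward map for `S = L L^T`), so they are exact for the
approximation being optimized; both pieces are verified against finite
differences in the unit tests.

**Inducing posterior q(u).**  Gaussian per latent dimension with the exact
coordinate-ascent optimum available in closed form from weighted node-level
accumulators `Phi_2 = sum_t w_t psi_2(t)` and
`Phi_1[:,k] = sum_t w_t E[k(x,Z) (A x + b - B v)_k]`:

    S_k* = ( K_zz^{-1} + sigma_k^{-2} K_zz^{-1} Phi_2 K_zz^{-1} )^{-1},
    m_k* = sigma_k^{-2} S_k* K_zz^{-1} Phi_1[:,k],

implemented through the Cholesky factor of `K_zz` so `S_k*` is PSD by
construction.  The update is checked against brute-force numeric ELBO
maximization on a small instance.

**Hyperparameters.**  Kernel hyperparameters are learned by maximizing the
partially optimized ELBO `max_Theta max_{q(u)} ELBO` with the inner
maximization re-solved in closed form at every objective evaluation; by the
envelope theorem the collapsed objective needs no gradient through the inner
argmax.  The quadrature nodes and the variational-drift values at the nodes
do not depend on `Theta`, so one objective evaluation reduces to a batched
kernel evaluation over all nodes plus `M x M` linear algebra.  With no
autodiff backend available, the outer optimization uses scipy L-BFGS-B with
finite-difference gradients on an unconstrained reparameterization (log for
`M_diag`, `sigma0^2`, `tau`; free for centers and boundary weights), a small
iteration cap per vEM sweep, and acceptance only when the collapsed objective
does not worsen.  `tau` is fixed by default (its gradient landscape is stiff
near zero) and can be learned on request.

**Observation parameters.**  Gaussian case: exact closed-form update of
`(C, d, R)` from the path moments.  Point-process case: the expected
log-likelihood is concave in each `(c_d, d_d)` (closed form under the
exponential link: `E[log lambda] = c^T m + d`,
`E[lambda] = exp(c^T m + d + c^T S c / 2)`), updated by damped Newton with a
small ridge on `c_d` for well-posedness when the latents carry little signal.
The intensity integral of the continuous-time likelihood is discretized by
the trapezoidal rule; event times are assigned to their nearest grid point.

**Process noise.**  Diagonal `Sigma` is learned by default with a
backtracking gradient step on the full ELBO; because `Sigma` enters both the
prior and the `q(x)` process, the forward moments are re-integrated for every
candidate and a step is accepted only if the ELBO improves.  In practice
`Sigma` first inflates (absorbing drift mismatch early in the fit) and then
contracts toward the generative value as the drift estimate improves;
clamping it small from the start traps the fit in poor optima.

**Initialization.**  `C, d` come from PCA of centered traces (Gaussian case)
or from a Poisson linear dynamical system with identity (random-walk)
dynamics fitted by MAP alternation on 20 ms binned counts (point-process
case), with latents standardized each alternation to pin down the
`C <-> x` scale degeneracy.  Inducing points form a regular grid over the
initialized latent range; regime centers start at k-means centroids of the
initialized latents; boundary weights are seed-jittered unit vectors;
`q(u)` starts at the prior.  `n_init` restarts (default 5) are run and the
best final ELBO kept.

## Analysis

`predict_dynamics` gives the drift posterior at arbitrary query points by
conditional-Gaussian algebra in O(N M^2).  The fixed-point probability map is
`prod_k P(|f_k(x)| < eps)` with `eps` defaulting to 5% of the median
posterior-mean drift magnitude.  `slow_point_map` evaluates it on a grid
restricted to the region the inferred latents traverse: outside that region
the posterior reverts to the diffuse GP prior and a high probability reflects
prior mass at zero rather than evidence for a fixed point.  Regime maps
threshold `max_j pi_j(x)` (default 0.5); points where no regime exceeds the
threshold form the boundary set.  For synthetic data, latent and dynamics
errors are reported after resolving the affine non-identifiability of the
latent space with a least-squares affine map from inferred to true latents
(the dynamics field transforms with the same map).  Forward-simulation R^2
integrates the posterior-mean drift deterministically (no injected process
noise) from inferred latents spaced a fixed number of bins apart.

## Synthetic data

`make_two_rotation_dataset` is the benchmark generator: a clockwise linear
rotational system centered at (3, 0) and a counterclockwise one at (-3, 0),
joined smoothly at the boundary x1 = 0 (softmax temperature 1), with rotation
speed 2.5 rad/s, contraction 0.25 1/s, process noise 0.1 per dimension,
initial states uniform over [-6, 6] x [-4, 4], and Poisson-process
observations with random loadings around a 10 Hz baseline.  Defaults are 30
trials, 50 output channels, 2.5 s horizon at a 1 ms simulation step;
Euler-Maruyama for the latent path and Lewis-Shedler thinning against a
per-step piecewise-constant intensity bound for event times (preserving
continuous event times for the continuous-time likelihood).
`make_limit_cycle_dataset` provides a radial limit cycle
(`r' = r (1 - (r/R)^2)`, `theta' = omega`) whose circular regime boundary
exercises the quadratic feature map; it is a synthetic stand-in for
limit-cycle dynamics, not a reproduction of any particular dataset.

What the generators emulate: low-dimensional smooth switching dynamics,
Poisson spiking with realistic rates, trial-to-trial variability through
diffusion noise and random starts.  What they do not: non-Poisson spiking
statistics (refractoriness, bursting), heavy-tailed or correlated observation
noise, non-stationary tuning, and latent dimensionality misspecification —
so passing recovery tests shows the estimator works under its own model
class, not that real recordings satisfy these assumptions.

## Numerical choices

- Tensor-product Gauss-Hermite order: 10 for standalone psi-statistic calls,
  6 inside fitting loops (nodes = order^K); the latent dimension is capped at
  K <= 3 because the grid grows exponentially.  For very sharp partitions
  (temperature well below the latent length scale) the integrand is close to
  discontinuous and order ~20 still carries relative errors of order 1e-3;
  smooth-regime accuracy (relative error < 1e-6 between orders 10 and 20) is
  what the tests certify.
- Jitter: a relative 1e-8 x mean-diagonal jitter is added before every
  Cholesky of an SSL Gram matrix (they are low-rank-plus-constant and
  routinely singular), escalating tenfold on failure.  GP *sampling* uses an
  exact eigen-factor instead, so that single-regime draws are affine to
  machine precision rather than jitter precision.
- Forward moment integration clips covariance eigenvalues at 1e-10 if a
  diagonal goes nonpositive and aborts (triggering damping) if moments
  exceed 1e8.
- Log-intensities are capped at 50 inside expected-rate computations: beyond
  that the candidate state is being rejected anyway, and a finite value keeps
  the damped acceptance logic in control.
- All randomness flows from integer seeds through `numpy` `SeedSequence`
  spawning; fits are bit-reproducible given the configuration.

## Problem sizes in the test suite and acceptance script

The recovery experiments use a scaled-down benchmark chosen as the smallest
size at which the qualitative results are stable: 10 trials, 20 output
channels, 2 s horizon at a 10 ms grid, J = 2, K = 2, M = 36 inducing points,
15 vEM iterations, best of 2 restarts, with the RBF baseline fitted under the
identical budget.  Longer fits (30 iterations, 3 restarts) sharpen the
numbers (boundary angle well under 1 degree) but do not change any ordering.

## Known limitations

- Memory and time of the quadrature grid scale as order^K; K > 3 is not
  supported.
- Variational posteriors of this family underestimate path and dynamics
  uncertainty; fixed-point probability maps inherit that optimism.
- Fixed-point localization is limited by data coverage near the slow regions;
  at the scaled-down benchmark size the slow-point blob for a regime whose
  neighborhood is sparsely visited can sit a few tenths of a latent unit from
  the true equilibrium.
- Inducing locations are fixed on a grid, not optimized.
- The E-step is sequential in time; no parallel-in-time or amortized updates.
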