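# gpslds

Gaussian Process Switching Linear Dynamical Systems for latent neural
dynamics.

Neural population recordings — spike trains or imaging traces from tens to
hundreds of channels — are commonly summarized by a low-dimensional latent
state whose dynamics implement the computation under study.  Two modeling
goals pull against each other: expressive nonlinear dynamics, and the
interpretability of linear systems.  The gpSLDS balances them: the latent
state follows a continuous-time SDE

    dx = ( f(x) + B v_t ) dt + Sigma^{1/2} dw,

whose drift `f` carries a Gaussian-process prior under the **smoothly
switching linear (SSL) kernel**

    k(x, x') = sum_{j=1}^{J} [ (x - c_j)^T M (x' - c_j) + sigma0^2 ]
               pi_j(x) pi_j(x'),
    pi_j(x)  = softmax_j( w_j^T phi(x) / tau ),

so that flow fields are locally linear within `J` regimes and interpolate
smoothly across softmax decision boundaries — the structure of a recurrent
switching linear dynamical system, with full posterior uncertainty over the
dynamics.  Observations are per-channel Poisson processes with intensity
`exp(c_d^T x + d_d)` (spikes, handled in continuous time) or Gaussian samples
`N(C x + d, R)` (traces).  Fitting is variational EM: a Gaussian-process path
posterior updated by forward-backward smoothing sweeps, closed-form updates
of a sparse inducing-point posterior over drift values, and kernel
hyperparameters learned on the partially optimized ELBO
`max_Theta max_{q(u)} L` with the inner maximization solved analytically.
Fitted models expose flow fields with uncertainty, regime partitions, and
fixed-point probability maps (e.g. for line-attractor evidence).

Audience: computational neuroscientists analyzing multi-trial population
recordings, and methods researchers working on GP-based state-space models.

See `docs/methods.md` for the model, inference scheme, and numerical choices.

## Worked example

Fit the two-rotation benchmark (two linear rotational systems, one clockwise
and one counterclockwise, joined smoothly at the boundary x1 = 0) from
Poisson-process observations, and compare against the known ground truth:

```python
import numpy as np
from gpslds import GPSLDS, make_two_rotation_dataset
from gpslds.analysis import latent_and_dynamics_mse, slow_point_map

trials, truth = make_two_rotation_dataset(n_trials=10, n_outputs=20,
                                          duration=2.0, dt=0.01, seed=0)
model = GPSLDS(n_latents=2, n_regimes=2, n_inducing=36, dt_inference=0.01,
               vem_iterations=15, n_init=2, quad_order=5, seed=0)
model.fit(trials)                       # ~6 minutes on one core
print(f"final ELBO: {model.score():.1f}")

lat_mse, dyn_mse, (W, o) = latent_and_dynamics_mse(model.state_, truth)
print(f"latent MSE (after affine alignment): {lat_mse:.3f}")
print(f"dynamics MSE on visited region:      {dyn_mse:.3f}")

w = model.kernel_params_.boundary_weights[0][:2]
n_fit = np.linalg.solve(W.T, w)
angle = np.degrees(np.arccos(abs(n_fit @ truth.boundary_normal)
                             / np.linalg.norm(n_fit)))
print(f"boundary angle error: {angle:.2f} degrees")
grid, prob = slow_point_map(model.state_)
best = grid[np.argmax(prob)] @ W.T + o
print(f"most probable fixed point (true coords): {np.round(best, 2)}, "
      f"P = {prob.max():.2f}")
```

Output:

```
final ELBO: 7524.9
latent MSE (after affine alignment): 0.262
dynamics MSE on visited region:      0.614
boundary angle error: 0.97 degrees
most probable fixed point (true coords): [-3.45  0.12], P = 0.98
```

The latent space is identifiable only up to an affine transformation, so all
ground-truth comparisons go through the least-squares alignment `(W, o)`.
Here the fitted decision boundary is within a degree of the true x1 = 0
plane; the dynamics MSE of 0.61 compares with true drift magnitudes of
several units per second over the visited region; and the highest
fixed-point-probability location lands close to the true equilibrium at
(-3, 0) (about 0.45 latent units, reflecting data coverage near that regime).

The same model class fits Gaussian traces (set trials with `sample_times` /
`observations`), learns an input map `B` from known input signals, and
supports nonlinear regime boundaries through the quadratic feature map
(`feature_map="quadratic"`, exercised by the `make_limit_cycle_dataset`
generator).

## Command line

```bash
gpslds simulate --config run.yaml     # write dataset.h5 (+ ground truth record)
gpslds fit      --config run.yaml     # vEM fit -> fit_state.h5, elbo_trace.csv
gpslds analyze  --config run.yaml     # flow field, regime & fixed-point maps,
                                      # forward-simulation R^2, report.json
```

The YAML config has `dataset`, `model`, `fit`, `analyze` sections and an
output directory; the fully resolved config is echoed into the output
directory so a run can be reproduced exactly.

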