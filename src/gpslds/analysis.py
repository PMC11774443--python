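"""Post-hoc analysis of a fitted model: flow fields, regimes, fixed points.

The fitted model gives a Gaussian posterior over the drift value at any query
point through the inducing posterior.  From it we derive regime-partition
maps, a fixed-point probability map (the per-point probability that every
drift component lies within ``(-eps, eps)``), forward-simulation accuracy,
and ground-truth error metrics for synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve
from scipy.stats import norm

from .inference import FitState, InducingPosterior
from .kernels import SSLKernelParams, jittered_cholesky, make_kernel, partition_weights
from .simulate import GPSLDSModel

__all__ = [
    "DynamicsPosterior",
    "predict_dynamics",
    "fixed_point_probability",
    "regime_map",
    "forward_simulation_r2",
    "r_squared",
    "latent_and_dynamics_mse",
    "affine_alignment",
    "slow_point_map",
]


@dataclass
class DynamicsPosterior:
    """Posterior over the drift at query points."""

    query_points: np.ndarray   # (N, K)
    mean: np.ndarray           # (N, K)
    var: np.ndarray            # (N, K) per-dimension posterior variance
    regime_probs: np.ndarray | None  # (N, J) for SSL kernels


def predict_dynamics(model: GPSLDSModel, q_u: InducingPosterior,
                     X: np.ndarray) -> DynamicsPosterior:
    """Sparse-GP posterior of the drift at query points (O(N M^2) batch cost).

    Per latent dimension ``k``: ``q(f_k*) = int p(f_k*|u_k) q(u_k) du_k``,
    a Gaussian obtained by conditional-Gaussian algebra on the kernel.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = model.inducing_locations
    kernel = make_kernel(model.kernel)
    Lzz = jittered_cholesky(kernel.gram(Z))
    kxz = kernel.gram(X, Z)                       # (N, M)
    kdiag = kernel.diag(X)
    sol = cho_solve((Lzz, True), kxz.T)           # Kzz^-1 Kzx, (M, N)
    k_lat = q_u.mean.shape[0]
    mean = np.empty((X.shape[0], k_lat))
    var = np.empty((X.shape[0], k_lat))
    base = kdiag - np.sum(kxz.T * sol, axis=0)    # k(x,x) - k_xz Kzz^-1 k_zx
    for k in range(k_lat):
        mean[:, k] = kxz @ cho_solve((Lzz, True), q_u.mean[k])
        corr = np.sum(sol * (q_u.cov[k] @ sol), axis=0)
        var[:, k] = np.maximum(base + corr, 0.0)
    regime = None
    if isinstance(model.kernel, SSLKernelParams):
        regime = np.atleast_2d(partition_weights(X, model.kernel))
    return DynamicsPosterior(query_points=X, mean=mean, var=var, regime_probs=regime)


def fixed_point_probability(post: DynamicsPosterior, epsilon: float | None = None
                            ) -> np.ndarray:
    """Per-point probability that all drift components lie in ``(-eps, eps)``.

    With no ``epsilon`` given, it defaults to 5% of the median posterior-mean
    drift magnitude over the query points.
    """
    if epsilon is None:
        epsilon = 0.05 * float(np.median(np.linalg.norm(post.mean, axis=1)))
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    sd = np.sqrt(np.maximum(post.var, 1e-30))
    mass = norm.cdf((epsilon - post.mean) / sd) - norm.cdf((-epsilon - post.mean) / sd)
    return np.prod(np.clip(mass, 0.0, 1.0), axis=1)


def regime_map(params: SSLKernelParams, X: np.ndarray, threshold: float = 0.5):
    """Most-likely regime labels plus the boundary set where no regime wins.

    Returns ``(labels, boundary_mask)``; a point belongs to the boundary when
    its largest regime probability does not exceed ``threshold``.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    pi = np.atleast_2d(partition_weights(X, params))
    labels = np.argmax(pi, axis=1)
    boundary = np.max(pi, axis=1) <= threshold + 1e-12
    return labels, boundary


def forward_simulation_r2(state: FitState, horizon_steps: int, spacing: int,
                          q_u: InducingPosterior | None = None) -> float:
    """Forward-simulation accuracy of the fitted dynamics.

    Initial conditions are the inferred latent means spaced ``spacing`` grid
    bins apart; the posterior-mean drift is integrated deterministically for
    ``horizon_steps`` bins, mapped through the observation model, and compared
    to the observed data by pooled R^2.
    """
    q_u = q_u if q_u is not None else state.q_u
    model = state.model
    preds, truths = [], []
    for grid, path in zip(state.grids, state.q_paths):
        times = grid.times
        n = len(times)
        if grid.y is not None:
            data = grid.y
            data_idx = grid.obs_idx
        else:
            data = grid.counts / np.maximum(grid.weights[:, None], 1e-12)
            data_idx = np.arange(n)
        bv_all = None
        if grid.v is not None and model.input_map is not None:
            bv_all = grid.v @ model.input_map.T
        starts = list(range(0, n - 1, spacing))
        for s0 in starts:
            end = min(s0 + horizon_steps, n - 1)
            if end <= s0:
                continue
            x = path.marg_mean[s0].copy()
            xs = np.empty((end - s0 + 1, len(x)))
            xs[0] = x
            for i in range(s0, end):
                h = times[i + 1] - times[i]
                f = predict_dynamics(model, q_u, x[None, :]).mean[0]
                if bv_all is not None:
                    f = f + bv_all[i]
                x = x + h * f
                xs[i + 1 - s0] = x
            sel = (data_idx >= s0) & (data_idx <= end)
            if not np.any(sel):
                continue
            lat = xs[data_idx[sel] - s0]
            eta = lat @ model.obs_map.T + model.obs_offset
            if model.link_id == "exp":
                pred = np.exp(np.clip(eta, -30.0, 30.0))
            else:
                pred = eta
            preds.append(pred)
            truths.append(data[sel])
    if not preds:
        raise ValueError("no forward-simulation segments; check horizon and spacing")
    return r_squared(np.concatenate(preds).ravel(), np.concatenate(truths).ravel())


def r_squared(pred: np.ndarray, truth: np.ndarray) -> float:
    """Coefficient of determination, pooled over all entries."""
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    ss_res = np.sum((truth - pred) ** 2)
    ss_tot = np.sum((truth - truth.mean()) ** 2)
    return float(1.0 - ss_res / ss_tot)


def slow_point_map(state: FitState, q_u: InducingPosterior | None = None,
                   n_grid: int = 40, margin: float = 0.05,
                   data_radius: float | None = 0.3, epsilon: float | None = None):
    """Fixed-/slow-point probability map over the visited latent region.

    Evaluates :func:`fixed_point_probability` on a regular ``n_grid x n_grid``
    grid spanning the inferred latent means (plus a fractional ``margin``),
    keeping only points within ``data_radius`` (in inferred latent units) of
    some inferred latent mean.  Away from the region the trajectories
    traverse, the drift posterior reverts toward the diffuse GP prior, and a
    high probability there reflects prior mass at zero rather than evidence
    for a fixed point — restricting to the visited region is what makes the
    map interpretable.  Pass ``data_radius=None`` to keep the whole grid.

    Returns ``(points, probabilities)``.
    """
    from scipy.spatial import cKDTree

    q_u = q_u if q_u is not None else state.q_u
    latents = np.concatenate([p.marg_mean for p in state.q_paths])
    if latents.shape[1] != 2:
        raise ValueError("slow-point maps are built for 2D latent spaces")
    lo, hi = latents.min(axis=0), latents.max(axis=0)
    span = hi - lo
    lo, hi = lo - margin * span, hi + margin * span
    axes = [np.linspace(lo[k], hi[k], n_grid) for k in range(2)]
    gx, gy = np.meshgrid(*axes, indexing="ij")
    points = np.column_stack([gx.ravel(), gy.ravel()])
    if data_radius is not None:
        dist, _ = cKDTree(latents).query(points)
        points = points[dist <= data_radius]
    post = predict_dynamics(state.model, q_u, points)
    return points, fixed_point_probability(post, epsilon)


def affine_alignment(inferred: np.ndarray, true: np.ndarray):
    """Least-squares affine map ``x_true ≈ W x_inf + o``; returns ``(W, o)``.

    The latent space is identifiable only up to an invertible affine
    transformation, so all ground-truth comparisons go through this map.
    """
    X = np.concatenate([inferred, np.ones((len(inferred), 1))], axis=1)
    sol, *_ = np.linalg.lstsq(X, true, rcond=None)
    return sol[:-1].T, sol[-1]


def latent_and_dynamics_mse(state: FitState, truth, q_u=None,
                            n_eval: int = 400, seed: int = 0):
    """MSE of inferred latents and dynamics against synthetic ground truth.

    Latent MSE is computed after resolving the affine non-identifiability by
    the best affine map from inferred to true latents.  Dynamics MSE compares
    the posterior-mean drift, pushed through the same map, with the true drift
    at points visited by the true latent paths.
    """
    q_u = q_u if q_u is not None else state.q_u
    inferred, true_lat = [], []
    for path, true_path in zip(state.q_paths, truth.latent_paths):
        tx = np.empty((len(path.times), true_path.shape[1]))
        for k in range(true_path.shape[1]):
            tx[:, k] = np.interp(path.times, truth.latent_times, true_path[:, k])
        inferred.append(path.marg_mean)
        true_lat.append(tx)
    inferred = np.concatenate(inferred)
    true_lat = np.concatenate(true_lat)
    W, o = affine_alignment(inferred, true_lat)
    aligned = inferred @ W.T + o
    latent_mse = float(np.mean((aligned - true_lat) ** 2))

    rng = np.random.default_rng(seed)
    visited = true_lat[rng.choice(len(true_lat), size=min(n_eval, len(true_lat)),
                                  replace=False)]
    Winv = np.linalg.inv(W)
    x_inf = (visited - o) @ Winv.T
    f_inf = predict_dynamics(state.model, q_u, x_inf).mean
    f_pushed = f_inf @ W.T
    f_true = np.atleast_2d(truth.drift(visited))
    dynamics_mse = float(np.mean((f_pushed - f_true) ** 2))
    return latent_mse, dynamics_mse, (W, o)
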