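"""Variational EM for the gpSLDS.

The approximate posterior factorizes as ``q(x) prod_k p(f_k|u_k) q(u_k)``.
``q(x)`` is a per-trial Gaussian process generated by a linear time-varying
SDE with drift ``A(t) x + b(t)`` and the model's diffusion; its marginals
``(m(t), S(t))`` obey forward moment equations, and the optimal controls
``(A(t), b(t))`` are found by a forward-backward sweep with Lagrange
multipliers (the variational smoothing scheme for diffusion processes), with
damped, monotonicity-guarded acceptance.  ``q(u_k)`` is Gaussian with exact
closed-form coordinate updates.  Kernel hyperparameters are learned by
maximizing the partially optimized ELBO ``max_Theta max_qu L(qx, qu, Theta)``,
re-solving the inner ``q(u)`` maximization analytically at every objective
evaluation.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize

from .drift import SparseGPDrift
from .kernels import (
    RBFKernel,
    RBFKernelParams,
    SSLKernel,
    SSLKernelParams,
    jittered_cholesky,
    make_kernel,
)
from .likelihoods import (
    GaussianLikelihood,
    GridObs,
    PointProcessLikelihood,
    build_grid_obs,
)
from .simulate import GPSLDSModel, TrialData

__all__ = [
    "VariationalPath",
    "InducingPosterior",
    "FitConfig",
    "FitState",
    "elbo",
    "update_qx",
    "update_qu",
    "update_input_map",
    "learn_hyperparams",
    "initialize",
    "fit",
]


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------

@dataclass
class VariationalPath:
    """Gaussian-process posterior over one trial's latent path.

    The path posterior is the linear time-varying SDE
    ``dx = (A(t) x + b(t)) dt + Sigma^{1/2} dw`` started from
    ``N(init_mean, init_cov)``; ``marg_mean``/``marg_cov`` cache the marginals
    obtained by integrating the forward moment equations on ``times``.
    """

    times: np.ndarray        # (N,)
    weights: np.ndarray      # (N,) trapezoid weights
    marg_mean: np.ndarray    # (N, K)
    marg_cov: np.ndarray     # (N, K, K)
    ctrl_lin: np.ndarray     # (N, K, K) A(t)
    ctrl_off: np.ndarray     # (N, K)    b(t)
    init_mean: np.ndarray    # (K,)
    init_cov: np.ndarray     # (K, K)


@dataclass
class InducingPosterior:
    """Gaussian posterior over inducing values, one block per latent dimension."""

    mean: np.ndarray  # (K, M)
    cov: np.ndarray   # (K, M, M)


@dataclass
class FitConfig:
    K: int = 2
    J: int = 2
    n_inducing: int = 36
    dt_inference: float = 5e-3
    vem_iterations: int = 30
    n_init: int = 5
    seed: int = 0
    quad_order: int = 6
    qx_sweeps: int = 1
    damping_init: float = 0.5
    m_step_maxiter: int = 8
    learn_temperature: bool = False
    learn_obs: bool = True
    learn_sigma: bool = True
    kernel_kind: str = "ssl"          # "ssl" or "rbf"
    feature_map_id: str = "affine"
    temperature: float = 1.0
    sigma0_sq: float = 0.1
    slope_var: float = 1.0
    process_noise: float = 0.1
    x0_prior_var: float = 16.0
    init_bin_dt: float = 20e-3
    elbo_rel_tol: float = 1e-6


@dataclass
class FitState:
    model: GPSLDSModel
    q_paths: list
    q_u: InducingPosterior
    elbo_trace: list
    config: FitConfig
    grids: list = field(default_factory=list)
    x0_prior_mean: np.ndarray | None = None
    x0_prior_cov: np.ndarray | None = None


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _likelihood(model: GPSLDSModel):
    if model.link_id == "exp":
        return PointProcessLikelihood(model.obs_map.copy(), model.obs_offset.copy())
    if model.link_id == "identity":
        nv = model.obs_noise_var if model.obs_noise_var is not None else np.ones(model.D)
        return GaussianLikelihood(model.obs_map.copy(), model.obs_offset.copy(), nv.copy())
    raise ValueError(f"no likelihood for link {model.link_id!r}")


def _drift_provider(state: FitState) -> SparseGPDrift:
    kernel = make_kernel(state.model.kernel, state.config.learn_temperature)
    return SparseGPDrift(
        kernel,
        state.model.inducing_locations,
        state.q_u.mean,
        state.q_u.cov,
        np.diag(state.model.noise_cov),
        quad_order=state.config.quad_order,
    )


def _bv(state: FitState, grid: GridObs) -> np.ndarray | None:
    if grid.v is None or state.model.input_map is None:
        return None
    return grid.v @ state.model.input_map.T


def _forward_pass(times, A, b, m0, S0, sigma_diag):
    n = len(times)
    k = len(m0)
    m = np.empty((n, k))
    S = np.empty((n, k, k))
    m[0], S[0] = m0, 0.5 * (S0 + S0.T)
    Sig = np.diag(sigma_diag)
    for i in range(n - 1):
        h = times[i + 1] - times[i]
        m[i + 1] = m[i] + h * (A[i] @ m[i] + b[i])
        Snew = S[i] + h * (A[i] @ S[i] + S[i] @ A[i].T + Sig)
        Snew = 0.5 * (Snew + Snew.T)
        if np.any(np.diag(Snew) <= 0.0):
            vals, vecs = np.linalg.eigh(Snew)
            Snew = (vecs * np.maximum(vals, 1e-10)) @ vecs.T
        if not np.isfinite(Snew).all() or np.trace(Snew) > 1e8:
            raise FloatingPointError(f"covariance integration diverged at step {i}")
        S[i + 1] = Snew
    if not np.all(np.isfinite(m)) or np.max(np.abs(m)) > 1e8:
        raise FloatingPointError("forward moment integration diverged")
    return m, S


def _gauss_kl(m0, S0, m1, S1) -> float:
    """KL( N(m0,S0) || N(m1,S1) )."""
    k = len(m0)
    L1 = jittered_cholesky(S1, 1e-12)
    sol = cho_solve((L1, True), S0)
    diff = np.asarray(m1) - np.asarray(m0)
    mahal = diff @ cho_solve((L1, True), diff)
    s, logdet0 = np.linalg.slogdet(S0)
    logdet1 = 2.0 * np.sum(np.log(np.diag(L1)))
    return 0.5 * (np.trace(sol) + mahal - k + logdet1 - logdet0)


def _trial_objective(state, grid, lik, drift, m, S, A, b, m0, S0) -> float:
    bv = _bv(state, grid)
    stats = drift.stats(m, S, A, b, bv, need_grads=False)
    ell = lik.expected_loglik(grid, m, S)
    kl0 = _gauss_kl(m0, S0, state.x0_prior_mean, state.x0_prior_cov)
    return ell - float(grid.weights @ stats.e) - kl0


def _kl_inducing(q_u: InducingPosterior, Kzz: np.ndarray) -> float:
    """KL(q(u_k) || N(0, Kzz)) summed over latent dimensions.

    Computed in whitened form W = L^-1 S_k L^-T so that the KL is exactly
    zero at the prior even when the SSL Gram matrix is numerically singular.
    """
    Lzz = jittered_cholesky(Kzz)
    m_ind = Kzz.shape[0]
    total = 0.0
    for k in range(q_u.mean.shape[0]):
        W = solve_triangular(Lzz, solve_triangular(Lzz, q_u.cov[k], lower=True).T,
                             lower=True)
        W = 0.5 * (W + W.T)
        mah = q_u.mean[k] @ cho_solve((Lzz, True), q_u.mean[k])
        sign, logdet_w = np.linalg.slogdet(W + 1e-12 * np.eye(m_ind))
        total += 0.5 * (np.trace(W) + mah - m_ind - logdet_w)
    return total


def elbo(state: FitState) -> float:
    """Evidence lower bound at the current variational posterior and parameters."""
    lik = _likelihood(state.model)
    drift = _drift_provider(state)
    total = 0.0
    for grid, path in zip(state.grids, state.q_paths):
        total += _trial_objective(
            state, grid, lik, drift,
            path.marg_mean, path.marg_cov, path.ctrl_lin, path.ctrl_off,
            path.init_mean, path.init_cov,
        )
    total -= _kl_inducing(state.q_u, drift.Kzz)
    if not np.isfinite(total):
        raise FloatingPointError("ELBO is not finite")
    return float(total)


# ---------------------------------------------------------------------------
# E-step: q(x) forward-backward update
# ---------------------------------------------------------------------------

def _backward_pass(times, weights, A, stats, gl_m, gl_S):
    n, k = gl_m.shape
    lam = np.zeros((n, k))
    psi = np.zeros((n, k, k))
    lam[-1] = gl_m[-1] - weights[-1] * stats.de_dm[-1]
    psi[-1] = gl_S[-1] - weights[-1] * stats.de_dS[-1]
    for i in range(n - 2, -1, -1):
        h = times[i + 1] - times[i]
        lam[i] = lam[i + 1] + h * (A[i].T @ lam[i + 1]) + gl_m[i] - weights[i] * stats.de_dm[i]
        p = psi[i + 1] + h * (A[i].T @ psi[i + 1] + psi[i + 1] @ A[i])
        psi[i] = 0.5 * (p + p.T) + gl_S[i] - weights[i] * stats.de_dS[i]
    return lam, psi


def update_qx(state: FitState, trial: int, n_sweeps: int | None = None,
              drift=None) -> VariationalPath:
    """One (or more) damped forward-backward sweeps on one trial's ``q(x)``.

    The proposed controls are blended with the current ones and accepted only
    if the trial's ELBO contribution does not decrease; the blending factor is
    halved on decrease, so the update is monotone by construction.  ``drift``
    overrides the drift-moment provider (e.g. a fixed linear drift for the
    exactly solvable linear-Gaussian case); by default the sparse-GP drift
    posterior implied by the current state is used.
    """
    cfg = state.config
    path = state.q_paths[trial]
    grid = state.grids[trial]
    lik = _likelihood(state.model)
    drift = drift if drift is not None else _drift_provider(state)
    sigma_diag = np.diag(state.model.noise_cov)
    Sig = np.diag(sigma_diag)
    n_sweeps = n_sweeps if n_sweeps is not None else cfg.qx_sweeps

    A, b = path.ctrl_lin.copy(), path.ctrl_off.copy()
    m0, S0 = path.init_mean.copy(), path.init_cov.copy()
    m, S = _forward_pass(path.times, A, b, m0, S0, sigma_diag)
    obj = _trial_objective(state, grid, lik, drift, m, S, A, b, m0, S0)
    bv = _bv(state, grid)
    V0_inv = np.linalg.inv(state.x0_prior_cov)

    for _ in range(n_sweeps):
        stats = drift.stats(m, S, A, b, bv, need_grads=True)
        gl_m, gl_S = lik.grads(grid, m, S)
        lam, psi = _backward_pass(path.times, grid.weights, A, stats, gl_m, gl_S)
        lam_next = np.concatenate([lam[1:], np.zeros((1, len(m0)))])
        psi_next = np.concatenate([psi[1:], np.zeros((1, len(m0), len(m0)))])
        A_star = stats.drift_jac + 2.0 * np.einsum("kl,nlj->nkj", Sig, psi_next)
        b_star = stats.drift_mean - np.einsum("nkl,nl->nk", A_star, m) + lam_next @ Sig.T
        m0_star = state.x0_prior_mean + state.x0_prior_cov @ lam[0]
        prec0 = V0_inv - 2.0 * psi[0]
        vals, vecs = np.linalg.eigh(0.5 * (prec0 + prec0.T))
        S0_star = (vecs / np.maximum(vals, 1e-8)) @ vecs.T

        # separately damped acceptance for the controls and the initial
        # condition: the multiplier-based initial-state proposal can overshoot
        # badly far from the optimum and would otherwise veto good control
        # updates
        accepted = False
        gamma = cfg.damping_init
        while gamma > 1e-7:
            A_new = (1 - gamma) * A + gamma * A_star
            b_new = (1 - gamma) * b + gamma * b_star
            try:
                m_new, S_new = _forward_pass(path.times, A_new, b_new, m0, S0, sigma_diag)
                obj_new = _trial_objective(
                    state, grid, lik, drift, m_new, S_new, A_new, b_new, m0, S0
                )
            except (FloatingPointError, np.linalg.LinAlgError, OverflowError):
                gamma *= 0.5
                continue
            if np.isfinite(obj_new) and obj_new >= obj - 1e-10 * (1.0 + abs(obj)):
                A, b, m, S, obj = A_new, b_new, m_new, S_new, obj_new
                accepted = True
                break
            gamma *= 0.5
        gamma = cfg.damping_init
        while gamma > 1e-7:
            m0_new = (1 - gamma) * m0 + gamma * m0_star
            S0_new = (1 - gamma) * S0 + gamma * S0_star
            try:
                m_new, S_new = _forward_pass(path.times, A, b, m0_new, S0_new, sigma_diag)
                obj_new = _trial_objective(
                    state, grid, lik, drift, m_new, S_new, A, b, m0_new, S0_new
                )
            except (FloatingPointError, np.linalg.LinAlgError, OverflowError):
                gamma *= 0.5
                continue
            if np.isfinite(obj_new) and obj_new >= obj - 1e-10 * (1.0 + abs(obj)):
                m0, S0, m, S, obj = m0_new, S0_new, m_new, S_new, obj_new
                accepted = True
                break
            gamma *= 0.5
        if not accepted:
            break

    return VariationalPath(
        times=path.times, weights=path.weights, marg_mean=m, marg_cov=S,
        ctrl_lin=A, ctrl_off=b, init_mean=m0, init_cov=S0,
    )


# ---------------------------------------------------------------------------
# closed-form q(u) update
# ---------------------------------------------------------------------------

def _accumulate_qu_stats(state: FitState, drift: SparseGPDrift):
    Phi2 = None
    Phi1 = None
    a0 = 0.0
    G2 = None
    for grid, path in zip(state.grids, state.q_paths):
        p2, p1, a, g2 = drift.node_accumulators(
            path.marg_mean, path.marg_cov, path.ctrl_lin, path.ctrl_off,
            _bv(state, grid), grid.weights,
        )
        Phi2 = p2 if Phi2 is None else Phi2 + p2
        Phi1 = p1 if Phi1 is None else Phi1 + p1
        G2 = g2 if G2 is None else G2 + g2
        a0 += a
    return Phi2, Phi1, a0, G2


def _solve_qu(Lzz, Phi2, Phi1, sigma_diag):
    """Exact maximizer of the ELBO over Gaussian q(u_k), per latent dimension."""
    m_ind = Lzz.shape[0]
    T = solve_triangular(Lzz, solve_triangular(Lzz, Phi2, lower=True).T, lower=True)
    T = 0.5 * (T + T.T)
    means, covs = [], []
    for k in range(len(sigma_diag)):
        beta = 1.0 / sigma_diag[k]
        P = np.eye(m_ind) + beta * T
        cP = cho_factor(0.5 * (P + P.T))
        r = solve_triangular(Lzz, Phi1[:, k], lower=True)
        covs.append(Lzz @ cho_solve(cP, Lzz.T))
        means.append(beta * Lzz @ cho_solve(cP, r))
    cov = np.stack([0.5 * (c + c.T) for c in covs])
    return InducingPosterior(mean=np.stack(means), cov=cov)


def update_qu(state: FitState) -> InducingPosterior:
    """Closed-form coordinate update of the inducing-point posterior."""
    drift = _drift_provider(state)
    Phi2, Phi1, _, _ = _accumulate_qu_stats(state, drift)
    return _solve_qu(drift.Lzz, Phi2, Phi1, np.diag(state.model.noise_cov))


# ---------------------------------------------------------------------------
# closed-form input-map update
# ---------------------------------------------------------------------------

def update_input_map(state: FitState) -> np.ndarray:
    """Exact ELBO maximizer over the input map B given q(x), q(u)."""
    if state.model.input_map is None:
        raise ValueError("model carries no input map")
    drift = _drift_provider(state)
    n_in = state.model.input_map.shape[1]
    k_lat = state.model.K
    gram = np.zeros((n_in, n_in))
    rhs = np.zeros((k_lat, n_in))
    for grid, path in zip(state.grids, state.q_paths):
        if grid.v is None:
            continue
        stats = drift.stats(
            path.marg_mean, path.marg_cov, path.ctrl_lin, path.ctrl_off,
            bv=None, need_grads=False,
        )
        g_mean = np.einsum("nkl,nl->nk", path.ctrl_lin, path.marg_mean) + path.ctrl_off
        target = g_mean - stats.drift_mean           # (N, K), what B v should supply
        wv = grid.v * grid.weights[:, None]
        gram += wv.T @ grid.v
        rhs += (target * grid.weights[:, None]).T @ grid.v
    if np.linalg.matrix_rank(gram, tol=1e-10 * max(np.trace(gram), 1e-30)) < n_in:
        warnings.warn("input design is rank deficient; returning minimum-norm solution")
        B, *_ = np.linalg.lstsq(gram, rhs.T, rcond=None)
        return B.T
    return np.linalg.solve(gram, rhs.T).T


# ---------------------------------------------------------------------------
# hyperparameter learning on the partially optimized ELBO
# ---------------------------------------------------------------------------

def _collapsed_terms(kernel, Z, flat_nodes, wp, g_nodes, sigma_diag, G2):
    """Collapsed objective: path-energy + inducing KL at the optimal q(u)."""
    kv = kernel.gram(flat_nodes, Z)
    kd = kernel.diag(flat_nodes)
    Kzz = kernel.gram(Z)
    Lzz = jittered_cholesky(Kzz)
    Phi2 = (kv * wp[:, None]).T @ kv
    Phi1 = kv.T @ (g_nodes * wp[:, None])
    a0 = float(wp @ kd)
    m_ind = Z.shape[0]
    T = solve_triangular(Lzz, solve_triangular(Lzz, Phi2, lower=True).T, lower=True)
    T = 0.5 * (T + T.T)
    total = 0.0
    for k in range(len(sigma_diag)):
        beta = 1.0 / sigma_diag[k]
        P = np.eye(m_ind) + beta * T
        cP = cho_factor(0.5 * (P + P.T))
        r = solve_triangular(Lzz, Phi1[:, k], lower=True)
        Pinv_r = cho_solve(cP, r)
        Pinv = cho_solve(cP, np.eye(m_ind))
        tr_PinvT = float(np.trace(Pinv @ T))
        # path-energy term at q(u_k)*
        quad_m = beta**2 * (Pinv_r @ T @ Pinv_r)
        lin_m = beta * (r @ Pinv_r)
        e_term = 0.5 * beta * (
            a0 - np.trace(T) + tr_PinvT + quad_m - 2.0 * lin_m + G2[k]
        )
        # KL(q(u_k)* || p(u_k))
        sign, logdet_P = np.linalg.slogdet(0.5 * (P + P.T))
        kl = 0.5 * (
            np.trace(Pinv) + beta**2 * (Pinv_r @ Pinv_r) - m_ind + logdet_P
        )
        total += e_term + kl
    return total


def _gather_nodes(state: FitState, drift: SparseGPDrift):
    from .quadrature import batch_nodes

    flat_list, wp_list, g_list, G2 = [], [], [], 0.0
    for grid, path in zip(state.grids, state.q_paths):
        m, S = path.marg_mean, path.marg_cov
        nodes, xi, wq, _ = batch_nodes(m, S, state.config.quad_order)
        n, q, k = nodes.shape
        flat = nodes.reshape(n * q, k)
        wp = (grid.weights[:, None] * wq[None, :]).reshape(n * q)
        g = (
            np.einsum("nkl,nql->nqk", path.ctrl_lin, nodes) + path.ctrl_off[:, None, :]
        ).reshape(n * q, k)
        bv = _bv(state, grid)
        if bv is not None:
            g = g - np.repeat(bv, q, axis=0)
        flat_list.append(flat)
        wp_list.append(wp)
        g_list.append(g)
    flat_nodes = np.concatenate(flat_list)
    wp = np.concatenate(wp_list)
    g_nodes = np.concatenate(g_list)
    G2 = wp @ (g_nodes**2)
    return flat_nodes, wp, g_nodes, G2


def learn_hyperparams(state: FitState, n_steps: int | None = None):
    """Gradient-based ascent of ``Theta`` on the partially optimized ELBO.

    The inner maximization over ``q(u)`` is re-solved in closed form at every
    objective evaluation; the step is accepted only if the collapsed objective
    does not decrease.  Returns ``(kernel_params, q_u)`` with the inducing
    posterior already at its optimum for the returned hyperparameters.
    """
    cfg = state.config
    n_steps = n_steps if n_steps is not None else cfg.m_step_maxiter
    kernel = make_kernel(state.model.kernel, cfg.learn_temperature)
    drift = _drift_provider(state)
    Z = state.model.inducing_locations
    sigma_diag = np.diag(state.model.noise_cov)
    flat_nodes, wp, g_nodes, G2 = _gather_nodes(state, drift)

    def negobj(vec):
        try:
            kern = kernel.with_free_vector(vec)
            return _collapsed_terms(kern, Z, flat_nodes, wp, g_nodes, sigma_diag, G2)
        except (np.linalg.LinAlgError, FloatingPointError, ValueError):
            return 1e12

    x0 = kernel.free_vector()
    f0 = negobj(x0)
    if n_steps > 0:
        res = minimize(
            negobj, x0, method="L-BFGS-B",
            options={"maxiter": n_steps, "maxfun": 40 * n_steps, "eps": 1e-6},
        )
        x_best, f_best = (res.x, res.fun) if res.fun <= f0 else (x0, f0)
    else:
        x_best = x0
    kernel_new = kernel.with_free_vector(x_best)
    params_new = kernel_new.params
    # resync q(u) to its closed-form optimum under the accepted hyperparameters
    Kzz = kernel_new.gram(Z)
    Lzz = jittered_cholesky(Kzz)
    kv = kernel_new.gram(flat_nodes, Z)
    Phi2 = (kv * wp[:, None]).T @ kv
    Phi1 = kv.T @ (g_nodes * wp[:, None])
    q_u = _solve_qu(Lzz, Phi2, Phi1, sigma_diag)
    return params_new, q_u


def update_sigma(state: FitState, n_steps: int = 3) -> np.ndarray:
    """Backtracking gradient step on the diagonal process noise.

    The diffusion enters both the prior and the q(x) process, so the ELBO is
    re-evaluated with the forward moments re-integrated at each candidate;
    a candidate is accepted only if the full ELBO improves.
    """
    cfg = state.config
    log_s = np.log(np.diag(state.model.noise_cov).copy())

    def full_elbo(ls):
        st = copy.copy(state)
        st.model = copy.copy(state.model)
        st.model.noise_cov = np.diag(np.exp(ls))
        new_paths = []
        for path in state.q_paths:
            m, S = _forward_pass(
                path.times, path.ctrl_lin, path.ctrl_off,
                path.init_mean, path.init_cov, np.exp(ls),
            )
            new_paths.append(
                VariationalPath(path.times, path.weights, m, S, path.ctrl_lin,
                                path.ctrl_off, path.init_mean, path.init_cov)
            )
        st.q_paths = new_paths
        return elbo(st), new_paths, st.model

    best, best_paths, best_model = full_elbo(log_s)
    for _ in range(n_steps):
        grad = np.zeros_like(log_s)
        eps = 1e-4
        for k in range(len(log_s)):
            pert = log_s.copy()
            pert[k] += eps
            try:
                up, _, _ = full_elbo(pert)
            except FloatingPointError:
                up = -np.inf
            grad[k] = (up - best) / eps
        if not np.all(np.isfinite(grad)) or np.linalg.norm(grad) < 1e-12:
            break
        step = 0.5
        improved = False
        while step > 1e-4:
            cand = log_s + step * grad / max(np.linalg.norm(grad), 1.0)
            try:
                val, paths, model = full_elbo(cand)
            except FloatingPointError:
                step *= 0.5
                continue
            if val > best:
                log_s, best, best_paths, best_model = cand, val, paths, model
                improved = True
                break
            step *= 0.5
        if not improved:
            break
    state.q_paths = best_paths
    return np.exp(log_s)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _init_latents_gaussian(trials, grids, k_lat):
    y_all = np.concatenate([t.observations for t in trials])
    if y_all.shape[0] < k_lat:
        raise ValueError("fewer observations than latent dimensions")
    mean_y = y_all.mean(axis=0)
    yc = y_all - mean_y
    _, _, vt = np.linalg.svd(yc, full_matrices=False)
    C = vt[:k_lat].T                                     # (D, K), orthonormal columns
    d = mean_y
    resid = yc - (yc @ C) @ C.T
    noise_var = np.maximum(resid.var(axis=0), 1e-6)
    paths = []
    for trial, grid in zip(trials, grids):
        x_hat = (trial.observations - mean_y) @ C        # (n_s, K)
        xg = np.empty((len(grid.times), k_lat))
        for k in range(k_lat):
            xg[:, k] = np.interp(grid.times, trial.sample_times, x_hat[:, k])
        paths.append(xg)
    return C, d, noise_var, paths


def _init_latents_poisson(trials, grids, k_lat, bin_dt, seed, n_alternations=3):
    """Poisson LDS with identity dynamics, fit by MAP alternation on binned counts.

    Latent states follow a random walk (identity dynamics); given ``C, d`` the
    MAP path solves a concave problem by Newton with a block-banded prior, and
    given paths, ``C, d`` are updated by expected-Poisson regression.
    """
    rng = np.random.default_rng(seed)
    d_out = len(trials[0].events)
    binned = []
    for trial in trials:
        n_bins = max(int(round(trial.duration / bin_dt)), 1)
        edges = np.linspace(0.0, trial.duration, n_bins + 1)
        cnt = np.stack(
            [np.histogram(ev, bins=edges)[0] for ev in trial.events], axis=1
        ).astype(float)
        binned.append((cnt, 0.5 * (edges[:-1] + edges[1:])))
    total_time = sum(t.duration for t in trials)
    total_events = np.sum([np.concatenate([[len(e) for e in t.events]] ) for t in trials], axis=0)
    d0 = np.log(np.maximum(total_events / total_time, 1e-3))
    C0 = rng.normal(0.0, 0.01, size=(d_out, k_lat))
    x_paths = [np.zeros((cnt.shape[0], k_lat)) for cnt, _ in binned]
    q_rw = 0.3  # random-walk innovation variance per unit time

    for _ in range(n_alternations):
        # MAP latent paths given C, d
        for i, (cnt, _) in enumerate(binned):
            x_paths[i] = _map_poisson_path(cnt, C0, d0, bin_dt, q_rw, x_paths[i])
        # standardize latents (absorbing the shift/scale into C, d) so the
        # alternation cannot run away along the C <-> x scale degeneracy
        allx = np.concatenate(x_paths)
        mu = allx.mean(axis=0)
        sd = np.maximum(allx.std(axis=0), 1e-3)
        x_paths = [(x - mu) / sd for x in x_paths]
        d0 = d0 + C0 @ mu
        C0 = C0 * sd
        # Poisson regression of C, d given paths (zero path uncertainty)
        lik = PointProcessLikelihood(C0, d0)
        synth_grids = [
            GridObs(times=centers, weights=np.full(len(centers), bin_dt),
                    counts=cnt, y=None, obs_idx=None, v=None)
            for cnt, centers in binned
        ]
        marginals = [(x, np.zeros((len(x), k_lat, k_lat))) for x in x_paths]
        lik.update_params(synth_grids, marginals, n_newton=10, ridge=10.0)
        C0, d0 = lik.C, lik.d

    paths = []
    for (cnt, centers), x_hat, grid in zip(binned, x_paths, grids):
        xg = np.empty((len(grid.times), k_lat))
        for k in range(k_lat):
            xg[:, k] = np.interp(grid.times, centers, x_hat[:, k])
        paths.append(xg)
    return C0, d0, paths


def _map_poisson_path(cnt, C, d, bin_dt, q_rw, x_init, n_newton=15):
    """Newton MAP estimate of a random-walk latent path under Poisson counts."""
    n, k = x_init.shape[0], C.shape[1]
    x = x_init.copy().ravel()
    qi = 1.0 / (q_rw * bin_dt)
    # random-walk precision (block tridiagonal, identity blocks)
    eye = np.eye(k)

    def obj_grad(xf):
        X = xf.reshape(n, k)
        eta = X @ C.T + d
        eta = np.clip(eta, -30.0, 30.0)
        lam = np.exp(eta)
        obj = np.sum(cnt * eta) - bin_dt * np.sum(lam)
        g = (cnt - bin_dt * lam) @ C
        dx = np.diff(X, axis=0)
        obj -= 0.5 * qi * np.sum(dx * dx) + 0.5 * 1e-2 * np.sum(X[0] ** 2)
        g[:-1] += qi * dx
        g[1:] -= qi * dx
        g[0] -= 1e-2 * X[0]
        return obj, g.ravel(), lam

    from scipy.sparse import lil_matrix
    from scipy.sparse.linalg import spsolve

    obj, g, lam = obj_grad(x)
    for _ in range(n_newton):
        # block-tridiagonal Hessian (Poisson curvature + random-walk precision)
        H = lil_matrix((n * k, n * k))
        for i in range(n):
            Hi = bin_dt * (C * lam[i][:, None]).T @ C + 1e-9 * eye
            sl = slice(i * k, (i + 1) * k)
            H[sl, sl] += Hi
            if i > 0:
                pr = slice((i - 1) * k, i * k)
                H[sl, sl] += qi * eye
                H[pr, pr] += qi * eye
                H[sl, pr] -= qi * eye
                H[pr, sl] -= qi * eye
        H[:k, :k] += 1e-2 * eye
        try:
            step = spsolve(H.tocsc(), g)
        except Exception:
            break
        alpha = 1.0
        while alpha > 1e-6:
            cand = x + alpha * step
            o2, g2, lam2 = obj_grad(cand)
            if o2 >= obj:
                x, obj, g, lam = cand, o2, g2, lam2
                break
            alpha *= 0.5
        else:
            break
        if np.linalg.norm(g) < 1e-8 * (1.0 + abs(obj)):
            break
    return x.reshape(n, k)


def _inducing_grid(latents, n_inducing, k_lat):
    per_dim = max(int(round(n_inducing ** (1.0 / k_lat))), 2)
    lo = latents.min(axis=0)
    hi = latents.max(axis=0)
    span = np.maximum(hi - lo, 1e-3)
    lo -= 0.1 * span
    hi += 0.1 * span
    axes = [np.linspace(lo[k], hi[k], per_dim) for k in range(k_lat)]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([g.ravel() for g in mesh], axis=1)


def initialize(trials: list[TrialData], config: FitConfig, seed: int | None = None) -> FitState:
    """Build an initial :class:`FitState` from data.

    ``C, d`` come from PCA (Gaussian data) or a Poisson-LDS-with-identity-
    dynamics fit on binned counts (point-process data); inducing locations
    are a regular grid over the range of the initialized latents; ``q(u)``
    starts at the prior; boundary weights are seed-jittered.
    """
    if not trials:
        raise ValueError("empty dataset")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    k_lat = config.K
    grids = [build_grid_obs(t, config.dt_inference) for t in trials]
    point_process = trials[0].is_point_process

    obs_noise = None
    if point_process:
        C, d, init_paths = _init_latents_poisson(
            trials, grids, k_lat, config.init_bin_dt, seed
        )
        link = "exp"
    else:
        C, d, obs_noise, init_paths = _init_latents_gaussian(trials, grids, k_lat)
        link = "identity"

    all_lat = np.concatenate(init_paths)
    Z = _inducing_grid(all_lat, config.n_inducing, k_lat)

    if config.kernel_kind == "ssl":
        if config.J > 1:
            from sklearn.cluster import KMeans

            km = KMeans(n_clusters=config.J, n_init=4, random_state=int(rng.integers(2**31)))
            sub = all_lat[:: max(len(all_lat) // 2000, 1)]
            centers = km.fit(sub).cluster_centers_
            bw = rng.normal(0.0, 1.0, size=(config.J - 1,
                                            _feature_dim(k_lat, config.feature_map_id)))
            bw /= np.linalg.norm(bw, axis=1, keepdims=True)
        else:
            centers = np.zeros((1, k_lat))
            bw = np.zeros((0, _feature_dim(k_lat, config.feature_map_id)))
        kern_params = SSLKernelParams(
            M_diag=np.full(k_lat, config.slope_var),
            sigma0_sq=config.sigma0_sq,
            centers=centers,
            boundary_weights=bw,
            temperature=config.temperature,
            feature_map_id=config.feature_map_id,
        )
    elif config.kernel_kind == "rbf":
        span = all_lat.max(axis=0) - all_lat.min(axis=0)
        kern_params = RBFKernelParams(
            lengthscales=np.maximum(0.5 * span, 1e-2),
            variance=max(config.slope_var * float(np.mean(span) ** 2) * 0.25, 1e-2),
        )
    else:
        raise ValueError(f"unknown kernel kind {config.kernel_kind!r}")

    has_inputs = trials[0].input_times is not None
    input_map = None
    if has_inputs:
        n_in = trials[0].input_values.shape[1]
        input_map = np.zeros((k_lat, n_in))

    model = GPSLDSModel(
        kernel=kern_params,
        noise_cov=config.process_noise * np.eye(k_lat),
        obs_map=C,
        obs_offset=d,
        link_id=link,
        obs_noise_var=obs_noise,
        input_map=input_map,
        inducing_locations=Z,
    )

    # q(u) at the prior
    kernel = make_kernel(kern_params, config.learn_temperature)
    Kzz = kernel.gram(Z)
    q_u = InducingPosterior(
        mean=np.zeros((k_lat, Z.shape[0])),
        cov=np.stack([Kzz.copy() for _ in range(k_lat)]),
    )

    # variational paths that roughly track the initialized latents
    q_paths = []
    sigma_diag = np.diag(model.noise_cov)
    for grid, xg in zip(grids, init_paths):
        n = len(grid.times)
        A = np.tile(-np.eye(k_lat), (n, 1, 1))
        b = np.empty((n, k_lat))
        dxg = np.gradient(xg, grid.times, axis=0)
        b = dxg + xg                                     # so that A x + b ≈ dx/dt
        S0 = 0.1 * np.eye(k_lat)
        m, S = _forward_pass(grid.times, A, b, xg[0], S0, sigma_diag)
        q_paths.append(
            VariationalPath(times=grid.times, weights=grid.weights, marg_mean=m,
                            marg_cov=S, ctrl_lin=A, ctrl_off=b,
                            init_mean=xg[0], init_cov=S0)
        )

    x0_mean = np.mean([p.init_mean for p in q_paths], axis=0)
    state = FitState(
        model=model, q_paths=q_paths, q_u=q_u, elbo_trace=[], config=config,
        grids=grids, x0_prior_mean=x0_mean,
        x0_prior_cov=config.x0_prior_var * np.eye(k_lat),
    )
    return state


def _feature_dim(k, kind):
    from .kernels import feature_dim

    return feature_dim(k, kind)


# ---------------------------------------------------------------------------
# the vEM driver
# ---------------------------------------------------------------------------

def _sync_likelihood(state, lik):
    state.model.obs_map = lik.C
    state.model.obs_offset = lik.d
    if isinstance(lik, GaussianLikelihood):
        state.model.obs_noise_var = lik.noise_var


def fit(trials: list[TrialData], config: FitConfig, verbose: bool = False,
        callback=None) -> FitState:
    """Run vEM: per-trial q(x) sweeps, closed-form q(u), observation and
    hyperparameter updates; best of ``config.n_init`` restarts by final ELBO."""
    best_state = None
    root = np.random.SeedSequence(config.seed)
    init_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(config.n_init)]
    for restart, seed_i in enumerate(init_seeds):
        state = initialize(trials, config, seed=seed_i)
        state.elbo_trace.append(elbo(state))
        for it in range(config.vem_iterations):
            for t in range(len(trials)):
                state.q_paths[t] = update_qx(state, t)
            state.q_u = update_qu(state)
            if config.learn_obs:
                lik = _likelihood(state.model)
                lik.update_params(
                    state.grids,
                    [(p.marg_mean, p.marg_cov) for p in state.q_paths],
                )
                _sync_likelihood(state, lik)
            if state.model.input_map is not None:
                state.model.input_map = update_input_map(state)
            if config.m_step_maxiter > 0:
                params_new, q_u_new = learn_hyperparams(state)
                state.model.kernel = params_new
                state.q_u = q_u_new
            if config.learn_sigma:
                sig = update_sigma(state)
                state.model.noise_cov = np.diag(sig)
            state.elbo_trace.append(elbo(state))
            if verbose:
                print(f"[restart {restart}] iter {it + 1}: elbo = {state.elbo_trace[-1]:.3f}")
            if callback is not None:
                callback(state, restart, it)
        if best_state is None or state.elbo_trace[-1] > best_state.elbo_trace[-1]:
            best_state = state
    return best_state
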