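"""Observation likelihoods on the inference grid.

Both likelihoods expose the expected log-likelihood under the Gaussian
marginals ``x(t_n) ~ N(m_n, S_n)`` of the variational path, its gradients with
respect to those marginals (consumed by the adjoint pass of the path update),
and an M-step update of the output parameters ``C, d`` (and the Gaussian noise
variances).

For point-process data the continuous-time log-likelihood
``sum_events log lambda_d(t) - int lambda_d(t) dt`` is used with the intensity
integral discretized by the trapezoidal rule on the inference grid; event
times are associated with their nearest grid point.  With the exponential
link, expectations are closed form:
``E[log lambda] = c^T m + d`` and ``E[lambda] = exp(c^T m + d + c^T S c / 2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import TrialData

__all__ = ["GridObs", "build_grid_obs", "PointProcessLikelihood", "GaussianLikelihood"]


@dataclass
class GridObs:
    """A trial's observations re-indexed onto the inference grid."""

    times: np.ndarray            # (N,) grid times
    weights: np.ndarray          # (N,) trapezoid quadrature weights
    counts: np.ndarray | None    # (N, D) event counts per grid point (point process)
    y: np.ndarray | None         # (n_s, D) Gaussian observations
    obs_idx: np.ndarray | None   # (n_s,) grid index of each Gaussian sample
    v: np.ndarray | None         # (N, I) known input signal on the grid
    trial_id: int = 0


def trapezoid_weights(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    w = np.zeros_like(times)
    if len(times) > 1:
        dt = np.diff(times)
        w[:-1] += 0.5 * dt
        w[1:] += 0.5 * dt
    return w


def build_grid_obs(trial: TrialData, dt: float) -> GridObs:
    """Lay a uniform inference grid over a trial and bin its observations."""
    n = max(int(round(trial.duration / dt)), 1)
    times = np.linspace(0.0, trial.duration, n + 1)
    weights = trapezoid_weights(times)
    counts = y = obs_idx = None
    if trial.is_point_process:
        d_out = len(trial.events)
        counts = np.zeros((n + 1, d_out))
        for d, ev in enumerate(trial.events):
            if ev.size:
                idx = np.clip(np.round(ev / (times[1] - times[0])).astype(int), 0, n)
                np.add.at(counts[:, d], idx, 1.0)
    else:
        y = trial.observations
        obs_idx = np.clip(
            np.round(trial.sample_times / (times[1] - times[0])).astype(int), 0, n
        )
    v = trial.inputs_at(times)
    return GridObs(
        times=times, weights=weights, counts=counts, y=y, obs_idx=obs_idx, v=v,
        trial_id=trial.trial_id,
    )


class PointProcessLikelihood:
    """Poisson-process observations with exponential link."""

    def __init__(self, C: np.ndarray, d: np.ndarray):
        self.C = np.atleast_2d(np.asarray(C, dtype=float))
        self.d = np.asarray(d, dtype=float).ravel()

    def _expected_rate(self, m, S):
        lin = m @ self.C.T + self.d                      # (N, D)
        quad = 0.5 * np.einsum("dk,nkl,dl->nd", self.C, S, self.C)
        # cap the exponent: beyond this the state is getting rejected anyway,
        # and a finite value keeps the damped acceptance logic in control
        rate = np.exp(np.minimum(lin + quad, 50.0))
        return rate, lin

    def expected_loglik(self, grid: GridObs, m, S) -> float:
        rate, lin = self._expected_rate(m, S)
        if not np.all(np.isfinite(rate)):
            raise FloatingPointError("expected intensity is not finite in the likelihood term")
        return float(np.sum(grid.counts * lin) - grid.weights @ np.sum(rate, axis=1))

    def grads(self, grid: GridObs, m, S):
        """(dl/dm, dl/dS) of the total expected log-likelihood, per grid point."""
        rate, _ = self._expected_rate(m, S)
        wrate = rate * grid.weights[:, None]
        gm = grid.counts @ self.C - wrate @ self.C
        gS = -0.5 * np.einsum("nd,dk,dl->nkl", wrate, self.C, self.C)
        return gm, gS

    def update_params(self, grids, marginals, n_newton: int = 25, tol: float = 1e-10,
                      ridge: float = 1e-8):
        """Concave Newton update of ``(c_d, d_d)`` per output channel.

        ``marginals`` is a list of ``(m, S)`` aligned with ``grids``.  The
        expected log-likelihood is concave in ``(c_d, d_d)``, so a damped
        Newton iteration converges quickly and never decreases the objective.
        ``ridge`` penalizes ``|c_d|^2``, which keeps the step well-posed when
        the latents carry little signal (e.g. during initialization).
        """
        m_all = np.concatenate([m for m, _ in marginals])
        S_all = np.concatenate([S for _, S in marginals])
        w_all = np.concatenate([g.weights for g in grids])
        counts_all = np.concatenate([g.counts for g in grids])
        k = m_all.shape[1]
        for d in range(self.C.shape[0]):
            theta = np.concatenate([self.C[d], [self.d[d]]])
            cnt = counts_all[:, d]
            lin_data = np.concatenate([cnt @ m_all, [cnt.sum()]])

            def negobj_grad_hess(th):
                c, off = th[:k], th[k]
                Sc = S_all @ c                                     # (N, K)
                rate = np.exp(np.minimum(m_all @ c + off + 0.5 * (Sc @ c), 50.0))
                wr = w_all * rate
                obj = lin_data @ th - wr.sum() - 0.5 * ridge * (c @ c)
                u = np.concatenate([m_all + Sc, np.ones((len(wr), 1))], axis=1)
                grad = lin_data - wr @ u
                grad[:k] -= ridge * c
                hess = -(u * wr[:, None]).T @ u
                hess[:k, :k] -= np.einsum("n,nkl->kl", wr, S_all) + ridge * np.eye(k)
                return obj, grad, hess

            obj, grad, hess = negobj_grad_hess(theta)
            for _ in range(n_newton):
                try:
                    step = np.linalg.solve(hess - 1e-10 * np.eye(k + 1), grad)
                except np.linalg.LinAlgError:
                    break
                alpha = 1.0
                for _ in range(30):
                    cand = theta - alpha * step
                    o2, g2, h2 = negobj_grad_hess(cand)
                    if np.isfinite(o2) and o2 >= obj:
                        theta, obj, grad, hess = cand, o2, g2, h2
                        break
                    alpha *= 0.5
                else:
                    break
                if np.linalg.norm(grad) < tol * (1.0 + abs(obj)):
                    break
            self.C[d] = theta[:k]
            self.d[d] = theta[k]


class GaussianLikelihood:
    """Gaussian observations ``y ~ N(C x + d, diag(noise_var))``."""

    def __init__(self, C: np.ndarray, d: np.ndarray, noise_var: np.ndarray):
        self.C = np.atleast_2d(np.asarray(C, dtype=float))
        self.d = np.asarray(d, dtype=float).ravel()
        self.noise_var = np.asarray(noise_var, dtype=float).ravel()

    def expected_loglik(self, grid: GridObs, m, S) -> float:
        if grid.y is None or len(grid.y) == 0:
            return 0.0
        mo, So = m[grid.obs_idx], S[grid.obs_idx]
        resid = grid.y - mo @ self.C.T - self.d
        quad = np.einsum("dk,nkl,dl->nd", self.C, So, self.C)
        r = self.noise_var
        return float(
            -0.5 * np.sum((resid**2 + quad) / r)
            - 0.5 * grid.y.size * np.log(2 * np.pi)
            - 0.5 * len(grid.y) * np.sum(np.log(r))
        )

    def grads(self, grid: GridObs, m, S):
        gm = np.zeros_like(m)
        gS = np.zeros((len(m), m.shape[1], m.shape[1]))
        if grid.y is None or len(grid.y) == 0:
            return gm, gS
        mo = m[grid.obs_idx]
        resid = (grid.y - mo @ self.C.T - self.d) / self.noise_var
        np.add.at(gm, grid.obs_idx, resid @ self.C)
        half_prec = -0.5 * (self.C / self.noise_var[:, None]).T @ self.C
        np.add.at(gS, grid.obs_idx, np.broadcast_to(half_prec, (len(grid.y), *half_prec.shape)))
        return gm, gS

    def update_params(self, grids, marginals):
        """Closed-form update of ``C, d, noise_var`` given path marginals."""
        k = marginals[0][0].shape[1]
        mom = np.zeros((k + 1, k + 1))
        cross = np.zeros((self.C.shape[0], k + 1))
        n_obs = 0
        ysq = np.zeros(self.C.shape[0])
        for grid, (m, S) in zip(grids, marginals):
            if grid.y is None or len(grid.y) == 0:
                continue
            mo, So = m[grid.obs_idx], S[grid.obs_idx]
            mom[:k, :k] += So.sum(axis=0) + mo.T @ mo
            mom[:k, k] += mo.sum(axis=0)
            mom[k, :k] += mo.sum(axis=0)
            mom[k, k] += len(mo)
            cross += grid.y.T @ np.concatenate([mo, np.ones((len(mo), 1))], axis=1)
            ysq += np.sum(grid.y**2, axis=0)
            n_obs += len(mo)
        if n_obs == 0:
            return
        sol = np.linalg.solve(mom + 1e-10 * np.eye(k + 1), cross.T).T
        self.C, self.d = sol[:, :k], sol[:, k]
        # residual second moment gives the noise update
        expect_sq = np.einsum("di,ij,dj->d", sol, mom, sol)
        self.noise_var = np.maximum(
            (ysq - 2 * np.sum(sol * cross, axis=1) + expect_sq) / n_obs, 1e-8
        )
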