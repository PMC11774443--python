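"""Drift moments under the variational posterior.

The path update and the ELBO need, at every grid point with marginal
``x ~ N(m_n, S_n)`` and variational drift ``g(x) = A_n x + b_n``, the
"energy"

    e_n = 1/2 E[ (f(x) + B v - g(x))^T Sigma^{-1} (f(x) + B v - g(x)) ],

the drift mean ``E[f(x)]``, the expected Jacobian ``E[df/dx]``, and the
gradients of ``e_n`` with respect to ``(m_n, S_n)``.  ``SparseGPDrift``
computes these by Gauss-Hermite quadrature through the sparse posterior
``q(f_k | u_k)``; the gradients differentiate the quadrature rule itself
(nodes ``x = m + L xi`` with ``S = L L^T``), so they are exact for the
approximation being optimized.  ``FixedLinearDrift`` implements the same
interface in closed form for a known affine drift, which is the
linear-Gaussian special case used for exactness checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve, solve_triangular

from .kernels import Kernel, jittered_cholesky
from .quadrature import batch_nodes

__all__ = ["DriftStats", "SparseGPDrift", "FixedLinearDrift"]


@dataclass
class DriftStats:
    e: np.ndarray                 # (N,) energy per grid point
    drift_mean: np.ndarray        # (N, K) E[f(x)] + B v (total prior drift mean)
    drift_jac: np.ndarray | None  # (N, K, K) E[df/dx]
    de_dm: np.ndarray | None      # (N, K)
    de_dS: np.ndarray | None      # (N, K, K), gradient for symmetric variations


def _chol_backward(L: np.ndarray, Lbar: np.ndarray) -> np.ndarray:
    """Map a gradient w.r.t. the Cholesky factor L to one w.r.t. S = L L^T.

    Returns the symmetric gradient G with df = sum_ij G_ij dS_ij for symmetric
    perturbations dS.
    """
    P = np.tril(L.T @ np.tril(Lbar))
    P[np.diag_indices_from(P)] *= 0.5
    Linv = solve_triangular(L, np.eye(L.shape[0]), lower=True)
    G = Linv.T @ P @ Linv
    return 0.5 * (G + G.T)


class SparseGPDrift:
    """Posterior drift moments under ``q(f_k|u_k) q(u_k)`` with inducing points."""

    def __init__(self, kernel: Kernel, Z: np.ndarray, u_mean: np.ndarray,
                 u_cov: np.ndarray, sigma_diag: np.ndarray, quad_order: int = 6):
        self.kernel = kernel
        self.Z = np.atleast_2d(np.asarray(Z, dtype=float))
        self.u_mean = np.asarray(u_mean, dtype=float)      # (K, M)
        self.u_cov = np.asarray(u_cov, dtype=float)        # (K, M, M)
        self.sigma_diag = np.asarray(sigma_diag, dtype=float).ravel()
        self.quad_order = quad_order
        self.Kzz = kernel.gram(self.Z)
        self.Lzz = jittered_cholesky(self.Kzz)
        m = self.Z.shape[0]
        kzz_inv = cho_solve((self.Lzz, True), np.eye(m))
        self.alpha = cho_solve((self.Lzz, True), self.u_mean.T)  # (M, K)
        # B_k = Kzz^-1 - Kzz^-1 S_k Kzz^-1 enters the conditional variance
        self.Bmats = np.stack(
            [kzz_inv - kzz_inv @ self.u_cov[k] @ kzz_inv for k in range(self.u_mean.shape[0])]
        )

    def stats(self, m, S, A, b, bv=None, need_grads=True) -> DriftStats:
        n, k_lat = m.shape
        nodes, xi, wq, Ls = batch_nodes(m, S, self.quad_order)
        q = nodes.shape[1]
        flat = nodes.reshape(n * q, k_lat)
        kv = self.kernel.gram(flat, self.Z)                # (P, M)
        kd = self.kernel.diag(flat)                        # (P,)
        mean_f = kv @ self.alpha                           # (P, K)
        var_f = np.empty((n * q, k_lat))
        u_list = []
        for kk in range(k_lat):
            u = kv @ self.Bmats[kk]
            u_list.append(u)
            var_f[:, kk] = kd - np.sum(u * kv, axis=1)
        var_f = np.maximum(var_f, 0.0)
        g = (np.einsum("nkl,nql->nqk", A, nodes) + b[:, None, :]).reshape(n * q, k_lat)
        resid = mean_f - g
        if bv is not None:
            resid = resid + np.repeat(bv, q, axis=0)
        inv_sig = 1.0 / self.sigma_diag
        E_p = 0.5 * (resid**2 + var_f) @ inv_sig
        e = (E_p.reshape(n, q) @ wq)

        drift_mean = (mean_f.reshape(n, q, k_lat).transpose(2, 0, 1) @ wq).T
        if bv is not None:
            drift_mean = drift_mean + bv

        if not need_grads:
            return DriftStats(e=e, drift_mean=drift_mean, drift_jac=None,
                              de_dm=None, de_dS=None)

        gc = self.kernel.grad_cross(flat, self.Z)          # (P, M, K)
        gd = self.kernel.grad_diag(flat)                   # (P, K)
        # E[df_k/dx] via the quadrature of the posterior-mean Jacobian
        jac_mean = np.einsum("pmj,mk->pkj", gc, self.alpha)  # (P, K_out, K_in)
        drift_jac = np.einsum("nqkj,q->nkj", jac_mean.reshape(n, q, k_lat, k_lat), wq)

        dE_dx = np.zeros((n * q, k_lat))
        A_rep = np.repeat(A, q, axis=0)                    # (P, K, K)
        for kk in range(k_lat):
            dresid = jac_mean[:, kk, :] - A_rep[:, kk, :]
            dvar = gd - 2.0 * np.einsum("pmj,pm->pj", gc, u_list[kk])
            dE_dx += inv_sig[kk] * (resid[:, kk, None] * dresid + 0.5 * dvar)
        dE_dx = dE_dx.reshape(n, q, k_lat)
        de_dm = np.einsum("nqj,q->nj", dE_dx, wq)
        Lbar = np.einsum("nqj,ql,q->njl", dE_dx, xi, wq)   # gradient w.r.t. L
        de_dS = np.empty((n, k_lat, k_lat))
        for i in range(n):
            de_dS[i] = _chol_backward(Ls[i], Lbar[i])
        return DriftStats(e=e, drift_mean=drift_mean, drift_jac=drift_jac,
                          de_dm=de_dm, de_dS=de_dS)

    def node_accumulators(self, m, S, A, b, bv, weights):
        """Weighted node-level sums for the closed-form q(u) update.

        Returns ``(Phi2 (M, M), Phi1 (M, K), a0 scalar, G2 (K,))`` where
        Phi2 = sum_t w_t psi2(t), Phi1[:, k] = sum_t w_t E[k(x, Z) g~_k(x)],
        a0 = sum_t w_t psi0(t) and G2_k = sum_t w_t E[g~_k(x)^2], with
        ``g~ = g - B v`` the input-corrected variational drift.
        """
        n, k_lat = m.shape
        nodes, xi, wq, _ = batch_nodes(m, S, self.quad_order)
        q = nodes.shape[1]
        flat = nodes.reshape(n * q, k_lat)
        wp = (weights[:, None] * wq[None, :]).reshape(n * q)
        kv = self.kernel.gram(flat, self.Z)
        kd = self.kernel.diag(flat)
        g = (np.einsum("nkl,nql->nqk", A, nodes) + b[:, None, :]).reshape(n * q, k_lat)
        if bv is not None:
            g = g - np.repeat(bv, q, axis=0)
        Phi2 = (kv * wp[:, None]).T @ kv
        Phi1 = kv.T @ (g * wp[:, None])
        a0 = float(wp @ kd)
        G2 = wp @ (g**2)
        return Phi2, Phi1, a0, G2


class FixedLinearDrift:
    """Known affine drift ``f(x) = A0 x + b0``; exact moments and gradients."""

    def __init__(self, A0: np.ndarray, b0: np.ndarray, sigma_diag: np.ndarray):
        self.A0 = np.atleast_2d(np.asarray(A0, dtype=float))
        self.b0 = np.asarray(b0, dtype=float).ravel()
        self.sigma_diag = np.asarray(sigma_diag, dtype=float).ravel()

    def stats(self, m, S, A, b, bv=None, need_grads=True) -> DriftStats:
        n, k_lat = m.shape
        dA = self.A0[None, :, :] - A                        # (N, K, K)
        r = m @ self.A0.T + self.b0 - (np.einsum("nkl,nl->nk", A, m) + b)
        if bv is not None:
            r = r + bv
        inv_sig = 1.0 / self.sigma_diag
        quad = np.einsum("nkl,nlj,nkj->nk", dA, S, dA)      # (dA S dA^T)_kk
        e = 0.5 * ((r**2 + quad) @ inv_sig)
        drift_mean = m @ self.A0.T + self.b0
        if bv is not None:
            drift_mean = drift_mean + bv
        drift_jac = np.broadcast_to(self.A0, (n, k_lat, k_lat)).copy()
        if not need_grads:
            return DriftStats(e=e, drift_mean=drift_mean, drift_jac=drift_jac,
                              de_dm=None, de_dS=None)
        de_dm = np.einsum("nkl,nk->nl", dA, r * inv_sig)
        de_dS = 0.5 * np.einsum("nkl,k,nkj->nlj", dA, inv_sig, dA)
        de_dS = 0.5 * (de_dS + np.swapaxes(de_dS, 1, 2))
        return DriftStats(e=e, drift_mean=drift_mean, drift_jac=drift_jac,
                          de_dm=de_dm, de_dS=de_dS)
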