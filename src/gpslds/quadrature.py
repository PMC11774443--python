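"""Gauss-Hermite expectations of kernel evaluations (psi statistics).

The evidence lower bound needs expectations of kernel evaluations under the
Gaussian marginals of the variational path posterior,

    psi0 = E[k(x, x)],   psi1_m = E[k(x, z_m)],   psi2 = E[k(Z, x) k(x, Z)],

with ``x ~ N(mean, cov)``.  For the SSL kernel these have no closed form, so
they are computed on a tensor-product Gauss-Hermite grid after a Cholesky
transform of the covariance.  The grid has ``order**K`` nodes, which is why
the latent dimension is capped at K <= 3.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .kernels import Kernel, make_kernel

__all__ = ["KernelExpectations", "gauss_hermite_grid", "expected_kernel_stats"]

MAX_LATENT_DIM = 3


@dataclass(frozen=True)
class KernelExpectations:
    """psi statistics of a kernel under one Gaussian over the input point."""

    psi0: float
    psi1: np.ndarray  # (M,)
    psi2: np.ndarray  # (M, M)


@lru_cache(maxsize=32)
def _gh_1d(order: int):
    nodes, weights = np.polynomial.hermite.hermgauss(order)
    # physicists' convention: integral weight exp(-t^2); rescale for N(0, 1)
    return nodes * np.sqrt(2.0), weights / np.sqrt(np.pi)


def gauss_hermite_grid(dim: int, order: int):
    """Tensor-product nodes ``(order**dim, dim)`` and weights for ``N(0, I)``."""
    if order < 1:
        raise ValueError("quadrature order must be >= 1")
    if dim > MAX_LATENT_DIM:
        raise ValueError(
            f"latent dimension {dim} exceeds the supported maximum of "
            f"{MAX_LATENT_DIM}; the tensor-product quadrature grid grows as "
            f"order**K and becomes impractical beyond that"
        )
    n1, w1 = _gh_1d(order)
    grids = np.meshgrid(*([n1] * dim), indexing="ij")
    nodes = np.stack([g.ravel() for g in grids], axis=1)
    wgrids = np.meshgrid(*([w1] * dim), indexing="ij")
    weights = np.prod(np.stack([g.ravel() for g in wgrids], axis=1), axis=1)
    return nodes, weights


def _cov_factor(cov: np.ndarray, rel_jitter: float = 1e-8) -> np.ndarray:
    """Cholesky-like factor of a PSD covariance; zero covariance gives zeros."""
    cov = 0.5 * (cov + cov.T)
    k = cov.shape[0]
    tr = float(np.trace(cov))
    if tr <= 0.0:
        if np.any(np.abs(cov) > 1e-300):
            raise np.linalg.LinAlgError("covariance has nonpositive trace but nonzero entries")
        return np.zeros_like(cov)
    jitter = rel_jitter * tr / k
    try:
        return np.linalg.cholesky(cov + jitter * np.eye(k))
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"covariance not PSD after jitter {jitter:.3e} (trace {tr:.3e})"
        ) from err


def expected_kernel_stats(
    mean: np.ndarray,
    cov: np.ndarray,
    Z: np.ndarray,
    params,
    quad_order: int = 10,
) -> KernelExpectations:
    """psi statistics of a kernel under ``x ~ N(mean, cov)``.

    Deterministic given inputs; with zero covariance the statistics collapse
    to plain kernel evaluations at the mean.
    """
    mean = np.asarray(mean, dtype=float).ravel()
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    kernel = make_kernel(params)
    k = mean.shape[0]
    L = _cov_factor(cov)
    xi, w = gauss_hermite_grid(k, quad_order)
    nodes = mean[None, :] + xi @ L.T  # (Q, K)
    kd = kernel.diag(nodes)  # (Q,)
    kv = kernel.gram(nodes, Z)  # (Q, M)
    psi0 = float(w @ kd)
    psi1 = w @ kv
    psi2 = (kv * w[:, None]).T @ kv
    psi2 = 0.5 * (psi2 + psi2.T)
    return KernelExpectations(psi0=psi0, psi1=psi1, psi2=psi2)


def batch_nodes(means: np.ndarray, covs: np.ndarray, quad_order: int):
    """Quadrature nodes for a batch of Gaussians.

    Returns ``(nodes, xi, weights)`` with ``nodes (N, Q, K)``, the standard
    normal grid ``xi (Q, K)`` and weights ``(Q,)``.  Shared by the E-step and
    the collapsed hyperparameter objective.
    """
    means = np.asarray(means, dtype=float)
    covs = np.asarray(covs, dtype=float)
    n, k = means.shape
    xi, w = gauss_hermite_grid(k, quad_order)
    Ls = np.empty_like(covs)
    for i in range(n):
        Ls[i] = _cov_factor(covs[i])
    nodes = means[:, None, :] + np.einsum("nkl,ql->nqk", Ls, xi)
    return nodes, xi, w, Ls
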