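"""Kernels for GP priors over latent dynamics.

The central object is the smoothly switching linear (SSL) kernel

    k(x, x') = sum_j [ (x - c_j)^T M (x' - c_j) + sigma0^2 ] * pi_j(x) pi_j(x')

where ``pi(x)`` is a temperature-controlled softmax over ``J`` regimes with
decision boundaries ``w_j^T phi(x) = 0``.  A GP with this kernel produces
functions that are affine inside each regime and interpolate smoothly across
regime boundaries, which is what makes the fitted flow fields readable as a
set of linear dynamical systems.  A standard RBF kernel is provided behind the
same interface as the flexible, unstructured baseline.
"""

from __future__ import annotations

import abc
import json
from dataclasses import dataclass

import numpy as np
from scipy.special import softmax

__all__ = [
    "SSLKernelParams",
    "RBFKernelParams",
    "feature_map",
    "feature_jacobian",
    "partition_weights",
    "partition_gradient",
    "linear_kernel",
    "ssl_kernel",
    "gram_matrix",
    "Kernel",
    "SSLKernel",
    "RBFKernel",
    "jittered_cholesky",
]

_FEATURE_MAPS = ("affine", "quadratic")


def feature_map(X: np.ndarray, kind: str = "affine") -> np.ndarray:
    """Map latent points ``X (N, K)`` to boundary features ``phi(X) (N, F)``.

    ``affine`` gives ``(x, 1)`` (linear boundaries with offset); ``quadratic``
    adds all pairwise products ``x_a x_b`` for curved boundaries such as circles.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    if kind == "affine":
        return np.concatenate([X, np.ones((n, 1))], axis=1)
    if kind == "quadratic":
        iu = np.triu_indices(k)
        quad = (X[:, :, None] * X[:, None, :])[:, iu[0], iu[1]]
        return np.concatenate([X, quad, np.ones((n, 1))], axis=1)
    raise ValueError(f"unknown feature map {kind!r}; choose from {_FEATURE_MAPS}")


def feature_dim(K: int, kind: str = "affine") -> int:
    if kind == "affine":
        return K + 1
    if kind == "quadratic":
        return K + K * (K + 1) // 2 + 1
    raise ValueError(f"unknown feature map {kind!r}")


def feature_jacobian(X: np.ndarray, kind: str = "affine") -> np.ndarray:
    """Jacobian ``d phi / d x`` with shape ``(N, F, K)``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    f = feature_dim(k, kind)
    J = np.zeros((n, f, k))
    J[:, :k, :] = np.eye(k)
    if kind == "quadratic":
        iu = np.triu_indices(k)
        for idx, (a, b) in enumerate(zip(*iu)):
            row = k + idx
            J[:, row, a] += X[:, b]
            J[:, row, b] += X[:, a]
    return J


@dataclass(frozen=True)
class SSLKernelParams:
    """Hyperparameters of the smoothly switching linear kernel.

    Attributes
    ----------
    M_diag : (K,) nonnegative slope variances, one per latent dimension.
    sigma0_sq : minimum function variance, attained at the regime centers.
    centers : (J, K) regime centers ``c_j`` (the loci of minimum variance, and
        the fixed points of the mean dynamics within each regime).
    boundary_weights : (J-1, F) softmax weights ``w_j`` over boundary features;
        the last regime's weights are pinned to zero.
    temperature : softmax temperature ``tau``; small values sharpen boundaries
        toward piecewise-constant switching, large values flatten ``pi`` to 1/J.
    feature_map_id : "affine" or "quadratic" boundary features.
    """

    M_diag: np.ndarray
    sigma0_sq: float
    centers: np.ndarray
    boundary_weights: np.ndarray
    temperature: float = 1.0
    feature_map_id: str = "affine"

    def __post_init__(self):
        object.__setattr__(self, "M_diag", np.atleast_1d(np.asarray(self.M_diag, dtype=float)))
        object.__setattr__(self, "centers", np.atleast_2d(np.asarray(self.centers, dtype=float)))
        bw = np.asarray(self.boundary_weights, dtype=float)
        if bw.size == 0:
            bw = bw.reshape(0, feature_dim(self.centers.shape[1], self.feature_map_id))
        bw = np.atleast_2d(bw)
        object.__setattr__(self, "boundary_weights", bw)
        if np.any(self.M_diag < 0):
            raise ValueError("M_diag entries must be nonnegative")
        if not self.sigma0_sq > 0:
            raise ValueError("sigma0_sq must be positive")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        if self.feature_map_id not in _FEATURE_MAPS:
            raise ValueError(f"unknown feature map {self.feature_map_id!r}")
        K = self.centers.shape[1]
        if self.M_diag.shape != (K,):
            raise ValueError("M_diag length must equal latent dimension K")
        J = self.centers.shape[0]
        if self.boundary_weights.shape[0] != J - 1:
            raise ValueError("need J-1 boundary weight vectors")
        F = feature_dim(K, self.feature_map_id)
        if J > 1 and self.boundary_weights.shape[1] != F:
            raise ValueError(
                f"boundary weight length {self.boundary_weights.shape[1]} does not "
                f"match feature dimension {F} of map {self.feature_map_id!r}"
            )

    @property
    def K(self) -> int:
        return self.centers.shape[1]

    @property
    def J(self) -> int:
        return self.centers.shape[0]

    # JSON round-trip -------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "kernel": "ssl",
                "M_diag": self.M_diag.tolist(),
                "sigma0_sq": float(self.sigma0_sq),
                "centers": self.centers.tolist(),
                "boundary_weights": self.boundary_weights.tolist(),
                "temperature": float(self.temperature),
                "feature_map_id": self.feature_map_id,
            }
        )

    @classmethod
    def from_json(cls, doc: str) -> "SSLKernelParams":
        d = json.loads(doc)
        if d.get("kernel", "ssl") != "ssl":
            raise ValueError("not an SSL kernel document")
        return cls(
            M_diag=np.asarray(d["M_diag"]),
            sigma0_sq=d["sigma0_sq"],
            centers=np.asarray(d["centers"]),
            boundary_weights=np.asarray(d["boundary_weights"]),
            temperature=d["temperature"],
            feature_map_id=d["feature_map_id"],
        )


@dataclass(frozen=True)
class RBFKernelParams:
    """Squared-exponential kernel: ``variance * exp(-0.5 sum ((x-x')/ls)^2)``."""

    lengthscales: np.ndarray
    variance: float = 1.0

    def __post_init__(self):
        object.__setattr__(
            self, "lengthscales", np.atleast_1d(np.asarray(self.lengthscales, dtype=float))
        )
        if np.any(self.lengthscales <= 0) or self.variance <= 0:
            raise ValueError("lengthscales and variance must be positive")

    @property
    def K(self) -> int:
        return self.lengthscales.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "kernel": "rbf",
                "lengthscales": self.lengthscales.tolist(),
                "variance": float(self.variance),
            }
        )

    @classmethod
    def from_json(cls, doc: str) -> "RBFKernelParams":
        d = json.loads(doc)
        if d.get("kernel") != "rbf":
            raise ValueError("not an RBF kernel document")
        return cls(lengthscales=np.asarray(d["lengthscales"]), variance=d["variance"])


# ---------------------------------------------------------------------------
# softmax partition
# ---------------------------------------------------------------------------

def _logits(X: np.ndarray, params: SSLKernelParams) -> np.ndarray:
    """Full (N, J) logit matrix including the pinned zero logit of regime J."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if params.J == 1:
        return np.zeros((n, 1))
    phi = feature_map(X, params.feature_map_id)
    if phi.shape[1] != params.boundary_weights.shape[1]:
        raise ValueError("feature dimension mismatch between phi(x) and boundary weights")
    logits = phi @ params.boundary_weights.T / params.temperature
    return np.concatenate([logits, np.zeros((n, 1))], axis=1)


def partition_weights(x: np.ndarray, params: SSLKernelParams) -> np.ndarray:
    """Regime probabilities ``pi(x)`` (softmax over ``J`` regimes).

    Accepts a single point ``(K,)`` or a batch ``(N, K)``; returns ``(J,)`` or
    ``(N, J)`` accordingly.  Computed through a stable log-sum-exp.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if x.reshape(-1, params.K).shape[1] != params.K:
        raise ValueError("point dimension does not match kernel K")
    pi = softmax(_logits(x, params), axis=1)
    return pi[0] if single else pi


def partition_gradient(X: np.ndarray, params: SSLKernelParams) -> np.ndarray:
    """Gradient ``d pi_j / d x`` for a batch; shape ``(N, J, K)``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if params.J == 1:
        return np.zeros((n, 1, params.K))
    pi = softmax(_logits(X, params), axis=1)  # (N, J)
    W = np.concatenate(
        [params.boundary_weights, np.zeros((1, params.boundary_weights.shape[1]))]
    )  # (J, F)
    wbar = pi @ W  # (N, F)
    s = pi[:, :, None] * (W[None, :, :] - wbar[:, None, :]) / params.temperature  # (N, J, F)
    Jphi = feature_jacobian(X, params.feature_map_id)  # (N, F, K)
    return np.einsum("njf,nfk->njk", s, Jphi)


# ---------------------------------------------------------------------------
# kernel evaluations
# ---------------------------------------------------------------------------

def linear_kernel(x: np.ndarray, x2: np.ndarray, j: int, params: SSLKernelParams) -> float:
    """Regime-``j`` linear kernel ``(x-c_j)^T M (x'-c_j) + sigma0^2`` (``j`` is 1-based)."""
    if not 1 <= j <= params.J:
        raise ValueError(f"regime index {j} out of range 1..{params.J}")
    c = params.centers[j - 1]
    x = np.asarray(x, dtype=float).reshape(params.K)
    x2 = np.asarray(x2, dtype=float).reshape(params.K)
    return float((x - c) @ (params.M_diag * (x2 - c)) + params.sigma0_sq)


def ssl_kernel(x: np.ndarray, x2: np.ndarray, params: SSLKernelParams) -> float:
    """Pointwise SSL kernel value ``sum_j k_lin^j(x,x') pi_j(x) pi_j(x')``."""
    pi_x = partition_weights(x, params)
    pi_x2 = partition_weights(x2, params)
    total = 0.0
    for j in range(1, params.J + 1):
        total += linear_kernel(x, x2, j, params) * pi_x[j - 1] * pi_x2[j - 1]
    return float(total)


def _ssl_gram(X: np.ndarray, X2: np.ndarray, params: SSLKernelParams) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    pi_x = partition_weights(X, params)
    pi_x2 = partition_weights(X2, params)
    out = np.zeros((X.shape[0], X2.shape[0]))
    for j in range(params.J):
        c = params.centers[j]
        lin = ((X - c) * params.M_diag) @ (X2 - c).T + params.sigma0_sq
        out += lin * np.outer(pi_x[:, j], pi_x2[:, j])
    return out


def gram_matrix(X: np.ndarray, X2: np.ndarray | None, params) -> np.ndarray:
    """Batched kernel matrix ``k(X_i, X2_j)``; ``X2=None`` means ``X2 = X``."""
    if X2 is None:
        X2 = X
    if isinstance(params, SSLKernelParams):
        return _ssl_gram(X, X2, params)
    if isinstance(params, RBFKernelParams):
        return RBFKernel(params).gram(X, X2)
    raise TypeError(f"unsupported kernel parameter type {type(params)!r}")


def jittered_cholesky(mat: np.ndarray, rel_jitter: float = 1e-8) -> np.ndarray:
    """Lower Cholesky factor with jitter scaled to the mean diagonal.

    SSL Gram matrices are low-rank-plus-constant and frequently near-singular,
    so a relative jitter is added up front and escalated on failure.
    """
    mat = 0.5 * (mat + mat.T)
    scale = max(float(np.mean(np.diag(mat))), 1e-300)
    jitter = rel_jitter * scale
    for _ in range(8):
        try:
            return np.linalg.cholesky(mat + jitter * np.eye(mat.shape[0]))
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise np.linalg.LinAlgError(
        f"Cholesky failed even with jitter {jitter:.3e} (trace {np.trace(mat):.3e})"
    )


# ---------------------------------------------------------------------------
# object interface used by inference (uniform across kernel families)
# ---------------------------------------------------------------------------

class Kernel(abc.ABC):
    """Kernel with evaluations, input-gradients, and a free-parameter vector.

    The free-parameter vector is the unconstrained reparameterization used by
    the hyperparameter optimizer (log transforms for positives).
    """

    @abc.abstractmethod
    def gram(self, X: np.ndarray, X2: np.ndarray | None = None) -> np.ndarray: ...

    @abc.abstractmethod
    def diag(self, X: np.ndarray) -> np.ndarray: ...

    @abc.abstractmethod
    def grad_cross(self, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
        """``d k(x, z) / d x`` with shape ``(N, M, K)``."""

    @abc.abstractmethod
    def grad_diag(self, X: np.ndarray) -> np.ndarray:
        """``d k(x, x) / d x`` with shape ``(N, K)``."""

    @abc.abstractmethod
    def free_vector(self) -> np.ndarray: ...

    @abc.abstractmethod
    def with_free_vector(self, vec: np.ndarray) -> "Kernel": ...


class SSLKernel(Kernel):
    def __init__(self, params: SSLKernelParams, learn_temperature: bool = False):
        self.params = params
        self.learn_temperature = learn_temperature

    def gram(self, X, X2=None):
        return _ssl_gram(X, X2 if X2 is not None else X, self.params)

    def diag(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        pi = partition_weights(X, self.params)
        out = np.zeros(X.shape[0])
        for j in range(self.params.J):
            d = X - self.params.centers[j]
            lin = np.sum(d * d * self.params.M_diag, axis=1) + self.params.sigma0_sq
            out += lin * pi[:, j] ** 2
        return out

    def grad_cross(self, X, Z):
        p = self.params
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        pi_x = partition_weights(X, p)          # (N, J)
        pi_z = partition_weights(Z, p)          # (M, J)
        gpi = partition_gradient(X, p)          # (N, J, K)
        out = np.zeros((X.shape[0], Z.shape[0], p.K))
        for j in range(p.J):
            c = p.centers[j]
            lin = ((X - c) * p.M_diag) @ (Z - c).T + p.sigma0_sq   # (N, M)
            mz = p.M_diag * (Z - c)                                 # (M, K)
            out += (
                pi_z[None, :, j, None]
                * (
                    pi_x[:, None, j, None] * mz[None, :, :]
                    + lin[:, :, None] * gpi[:, None, j, :]
                )
            )
        return out

    def grad_diag(self, X):
        p = self.params
        X = np.atleast_2d(np.asarray(X, dtype=float))
        pi = partition_weights(X, p)
        gpi = partition_gradient(X, p)
        out = np.zeros_like(X)
        for j in range(p.J):
            d = X - p.centers[j]
            lin = np.sum(d * d * p.M_diag, axis=1) + p.sigma0_sq
            out += 2.0 * pi[:, j, None] ** 2 * (p.M_diag * d)
            out += 2.0 * (lin * pi[:, j])[:, None] * gpi[:, j, :]
        return out

    def free_vector(self):
        p = self.params
        parts = [
            np.log(np.maximum(p.M_diag, 1e-12)),
            [np.log(p.sigma0_sq)],
            p.centers.ravel(),
            p.boundary_weights.ravel(),
        ]
        if self.learn_temperature:
            parts.append([np.log(p.temperature)])
        return np.concatenate([np.asarray(q, dtype=float).ravel() for q in parts])

    def with_free_vector(self, vec):
        p = self.params
        vec = np.asarray(vec, dtype=float)
        i = 0
        m = np.exp(vec[i : i + p.K]); i += p.K
        s0 = float(np.exp(vec[i])); i += 1
        centers = vec[i : i + p.J * p.K].reshape(p.J, p.K); i += p.J * p.K
        nw = p.boundary_weights.size
        bw = vec[i : i + nw].reshape(p.boundary_weights.shape); i += nw
        tau = p.temperature
        if self.learn_temperature:
            tau = float(np.exp(vec[i])); i += 1
        newp = SSLKernelParams(
            M_diag=m, sigma0_sq=s0, centers=centers, boundary_weights=bw,
            temperature=tau, feature_map_id=p.feature_map_id,
        )
        return SSLKernel(newp, self.learn_temperature)


class RBFKernel(Kernel):
    def __init__(self, params: RBFKernelParams):
        self.params = params

    def _sq_dists(self, X, Z):
        Xs = X / self.params.lengthscales
        Zs = Z / self.params.lengthscales
        return (
            np.sum(Xs * Xs, axis=1)[:, None]
            - 2.0 * Xs @ Zs.T
            + np.sum(Zs * Zs, axis=1)[None, :]
        )

    def gram(self, X, X2=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = X if X2 is None else np.atleast_2d(np.asarray(X2, dtype=float))
        return self.params.variance * np.exp(-0.5 * np.maximum(self._sq_dists(X, Z), 0.0))

    def diag(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.full(X.shape[0], self.params.variance)

    def grad_cross(self, X, Z):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        kv = self.gram(X, Z)
        diff = (X[:, None, :] - Z[None, :, :]) / self.params.lengthscales**2
        return -kv[:, :, None] * diff

    def grad_diag(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.zeros_like(X)

    def free_vector(self):
        return np.concatenate(
            [np.log(self.params.lengthscales), [np.log(self.params.variance)]]
        )

    def with_free_vector(self, vec):
        vec = np.asarray(vec, dtype=float)
        k = self.params.K
        return RBFKernel(
            RBFKernelParams(lengthscales=np.exp(vec[:k]), variance=float(np.exp(vec[k])))
        )


def make_kernel(params, learn_temperature: bool = False) -> Kernel:
    if isinstance(params, SSLKernelParams):
        return SSLKernel(params, learn_temperature)
    if isinstance(params, RBFKernelParams):
        return RBFKernel(params)
    if isinstance(params, Kernel):
        return params
    raise TypeError(f"unsupported kernel parameter type {type(params)!r}")
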