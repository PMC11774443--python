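"""Synthetic benchmark datasets with known ground-truth dynamics.

``make_two_rotation_dataset`` reproduces the canonical two-regime benchmark:
a clockwise and a counterclockwise linear rotational system joined smoothly at
the boundary ``x1 = 0``, observed through per-neuron Poisson processes.  The
defaults (30 trials, 50 output channels, 2.5 s horizon) are the study
conditions of that benchmark.  ``make_limit_cycle_dataset`` provides a 2D
radial limit cycle whose single circular regime boundary exercises the
quadratic (nonlinear) boundary feature map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import SSLKernelParams, partition_weights
from .simulate import (
    GPSLDSModel,
    TrialData,
    sample_poisson_process_observations,
    simulate_latent_path,
)

__all__ = ["GroundTruth", "make_two_rotation_dataset", "make_limit_cycle_dataset"]


@dataclass
class GroundTruth:
    """True generative quantities kept alongside a synthetic dataset."""

    drift: object                    # callable R^K -> R^K (vectorized over rows)
    kernel_params: SSLKernelParams   # true partition/centers used to build the drift
    fixed_points: np.ndarray         # (n_fp, K)
    boundary_normal: np.ndarray | None  # (K,) normal of the linear boundary, if any
    latent_times: np.ndarray         # (N,) simulation grid shared by trials
    latent_paths: np.ndarray         # (n_trials, N, K)
    model: GPSLDSModel               # the generative model (C, d, Sigma, ...)
    regime_matrices: np.ndarray | None = None  # (J, K, K) per-regime linear dynamics


def _two_rotation_drift(params: SSLKernelParams, A_mats: np.ndarray):
    centers = params.centers

    def drift(x):
        arr = np.asarray(x, dtype=float)
        single = arr.ndim == 1
        X = np.atleast_2d(arr)
        pi = np.atleast_2d(partition_weights(X, params))
        out = np.zeros_like(X)
        for j in range(centers.shape[0]):
            out += pi[:, j, None] * (X - centers[j]) @ A_mats[j].T
        return out[0] if single else out

    return drift


def make_two_rotation_dataset(
    n_trials: int = 30,
    n_outputs: int = 50,
    duration: float = 2.5,
    dt: float = 1e-3,
    seed: int = 0,
    *,
    omega: float = 2.5,
    decay: float = 0.25,
    temperature: float = 1.0,
    process_noise: float = 0.1,
    base_rate_hz: float = 10.0,
) -> tuple[list[TrialData], GroundTruth]:
    """Two smoothly joined rotational regimes observed via Poisson processes.

    The true drift is ``f(x) = pi_1(x) A_1 (x - c_1) + pi_2(x) A_2 (x - c_2)``
    with ``A_1`` clockwise (regime x1 > 0, center c_1 = (3, 0)) and ``A_2``
    counterclockwise (x1 < 0, center c_2 = (-3, 0)); the softmax boundary is
    the vertical line x1 = 0.  ``omega`` [rad/s] is the rotation speed and
    ``decay`` [1/s] a weak contraction that keeps trajectories bounded.
    Returns ``(trials, ground_truth)``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    root = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(2 + n_trials)]
    rng_obs, rng_x0 = rngs[0], rngs[1]

    centers = np.array([[3.0, 0.0], [-3.0, 0.0]])
    boundary = np.array([[1.0, 0.0, 0.0]])  # w^T phi(x) = x1
    params = SSLKernelParams(
        M_diag=np.ones(2),
        sigma0_sq=0.1,
        centers=centers,
        boundary_weights=boundary,
        temperature=temperature,
    )
    A_cw = np.array([[-decay, omega], [-omega, -decay]])
    A_ccw = np.array([[-decay, -omega], [omega, -decay]])
    A_mats = np.stack([A_cw, A_ccw])
    drift = _two_rotation_drift(params, A_mats)

    # observation map: mild random loadings around a 10 Hz baseline rate
    C = rng_obs.normal(0.0, 0.15, size=(n_outputs, 2))
    d = np.full(n_outputs, np.log(base_rate_hz))
    model = GPSLDSModel(
        kernel=params,
        noise_cov=process_noise * np.eye(2),
        obs_map=C,
        obs_offset=d,
        link_id="exp",
    )

    x0s = np.column_stack(
        [rng_x0.uniform(-6.0, 6.0, n_trials), rng_x0.uniform(-4.0, 4.0, n_trials)]
    )
    trials: list[TrialData] = []
    paths = []
    times = None
    for i in range(n_trials):
        rng_i = rngs[2 + i]
        times, path = simulate_latent_path(
            model, drift, x0s[i], dt=dt, duration=duration, seed=rng_i
        )
        trial = sample_poisson_process_observations(
            times, path, model, seed=rng_i, trial_id=i
        )
        trials.append(trial)
        paths.append(path)

    truth = GroundTruth(
        drift=drift,
        kernel_params=params,
        fixed_points=centers.copy(),
        boundary_normal=np.array([1.0, 0.0]),
        latent_times=times,
        latent_paths=np.stack(paths),
        model=model,
        regime_matrices=A_mats,
    )
    return trials, truth


def make_limit_cycle_dataset(
    n_trials: int = 10,
    n_outputs: int = 30,
    duration: float = 4.0,
    dt: float = 1e-3,
    seed: int = 0,
    *,
    omega: float = 2.0,
    radius: float = 2.0,
    process_noise: float = 0.02,
    base_rate_hz: float = 10.0,
) -> tuple[list[TrialData], GroundTruth]:
    """Radial limit cycle: ``r' = r (1 - (r/radius)^2)``, ``theta' = omega``.

    A synthetic stand-in for a limit-cycle system whose regime boundary is the
    circle ``|x| = radius``; it pairs naturally with the quadratic boundary
    feature map, where the circle is a linear decision boundary in feature
    space.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    root = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(2 + n_trials)]
    rng_obs, rng_x0 = rngs[0], rngs[1]

    def drift(x):
        arr = np.asarray(x, dtype=float)
        single = arr.ndim == 1
        X = np.atleast_2d(arr)
        r2 = np.sum(X * X, axis=1, keepdims=True) / radius**2
        radial = (1.0 - r2) * X
        rot = omega * np.column_stack([-X[:, 1], X[:, 0]])
        out = radial + rot
        return out[0] if single else out

    # circular boundary |x|^2 = radius^2 expressed in quadratic features
    # phi(x) = (x1, x2, x1^2, x1 x2, x2^2, 1)
    boundary = np.array([[0.0, 0.0, -1.0, 0.0, -1.0, radius**2]])
    params = SSLKernelParams(
        M_diag=np.ones(2),
        sigma0_sq=0.1,
        centers=np.array([[0.0, 0.0], [0.0, 0.0]]),
        boundary_weights=boundary,
        temperature=1.0,
        feature_map_id="quadratic",
    )
    C = rng_obs.normal(0.0, 0.2, size=(n_outputs, 2))
    d = np.full(n_outputs, np.log(base_rate_hz))
    model = GPSLDSModel(
        kernel=params,
        noise_cov=process_noise * np.eye(2),
        obs_map=C,
        obs_offset=d,
        link_id="exp",
    )
    trials, paths = [], []
    times = None
    for i in range(n_trials):
        rng_i = rngs[2 + i]
        r0 = rng_x0.uniform(0.5 * radius, 1.5 * radius)
        th0 = rng_x0.uniform(0.0, 2 * np.pi)
        x0 = np.array([r0 * np.cos(th0), r0 * np.sin(th0)])
        times, path = simulate_latent_path(
            model, drift, x0, dt=dt, duration=duration, seed=rng_i
        )
        trials.append(
            sample_poisson_process_observations(times, path, model, seed=rng_i, trial_id=i)
        )
        paths.append(path)
    truth = GroundTruth(
        drift=drift,
        kernel_params=params,
        fixed_points=np.zeros((1, 2)),
        boundary_normal=None,
        latent_times=times,
        latent_paths=np.stack(paths),
        model=model,
    )
    return trials, truth


GENERATORS = {
    "two_rotation": make_two_rotation_dataset,
    "limit_cycle": make_limit_cycle_dataset,
}
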