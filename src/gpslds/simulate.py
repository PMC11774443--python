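"""Generative model: latent SDE simulation and observation sampling.

The latent state follows ``dx = (f(x) + B v_t) dt + Sigma^{1/2} dw`` and is
observed either through a Poisson process with intensity
``lambda_d(t) = exp(c_d^T x(t) + d_d)`` per output channel (spiking data) or
through Gaussian samples ``y ~ N(C x + d, R)`` on a regular time grid
(e.g. imaging traces).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import make_kernel

__all__ = [
    "GPSLDSModel",
    "TrialData",
    "simulate_latent_path",
    "sample_dynamics_from_prior",
    "sample_poisson_process_observations",
    "sample_gaussian_observations",
]

MAX_INTENSITY_HZ = 1e6


@dataclass
class GPSLDSModel:
    """Full generative specification: kernel prior, SDE noise and observation map.

    ``kernel`` holds the hyperparameters of the GP prior on the drift,
    ``noise_cov`` is the process-noise covariance Sigma (K, K), ``obs_map`` /
    ``obs_offset`` the affine output map (C, d), ``link_id`` the inverse link
    ("exp" for point-process intensities, "identity" for Gaussian traces),
    and ``inducing_locations`` the M points z_m that anchor sparse inference.
    """

    kernel: object
    noise_cov: np.ndarray
    obs_map: np.ndarray
    obs_offset: np.ndarray
    link_id: str = "exp"
    obs_noise_var: np.ndarray | None = None
    input_map: np.ndarray | None = None
    inducing_locations: np.ndarray | None = None

    def __post_init__(self):
        self.noise_cov = np.atleast_2d(np.asarray(self.noise_cov, dtype=float))
        self.obs_map = np.atleast_2d(np.asarray(self.obs_map, dtype=float))
        self.obs_offset = np.asarray(self.obs_offset, dtype=float).ravel()
        if self.link_id not in ("exp", "identity", "softplus"):
            raise ValueError(f"unknown link {self.link_id!r}")
        if self.obs_map.shape[0] != self.obs_offset.shape[0]:
            raise ValueError("obs_map and obs_offset disagree on output dimension")
        if self.obs_noise_var is not None:
            self.obs_noise_var = np.asarray(self.obs_noise_var, dtype=float).ravel()
        if self.input_map is not None:
            self.input_map = np.atleast_2d(np.asarray(self.input_map, dtype=float))
        if self.inducing_locations is not None:
            self.inducing_locations = np.atleast_2d(
                np.asarray(self.inducing_locations, dtype=float)
            )

    @property
    def K(self) -> int:
        return self.noise_cov.shape[0]

    @property
    def D(self) -> int:
        return self.obs_map.shape[0]


@dataclass
class TrialData:
    """One trial of observations on ``[0, duration]``.

    Point-process trials carry per-output event-time arrays in ``events``;
    Gaussian trials carry ``sample_times`` and an ``observations`` matrix
    (n_samples, D).  Optional known inputs are a piecewise-constant signal
    given by ``input_times`` / ``input_values``.
    """

    duration: float
    events: list | None = None
    sample_times: np.ndarray | None = None
    observations: np.ndarray | None = None
    input_times: np.ndarray | None = None
    input_values: np.ndarray | None = None
    trial_id: int = 0

    def __post_init__(self):
        if self.events is not None:
            self.events = [np.asarray(e, dtype=float).ravel() for e in self.events]
            for e in self.events:
                if e.size and (e.min() < 0 or e.max() > self.duration + 1e-12):
                    raise ValueError("event times must lie in [0, duration]")
        if self.sample_times is not None:
            self.sample_times = np.asarray(self.sample_times, dtype=float).ravel()
            if self.sample_times.size and (
                self.sample_times.min() < 0
                or self.sample_times.max() > self.duration + 1e-12
            ):
                raise ValueError("sample times must lie in [0, duration]")
            self.observations = np.atleast_2d(np.asarray(self.observations, dtype=float))
        if self.input_times is not None:
            self.input_times = np.asarray(self.input_times, dtype=float).ravel()
            self.input_values = np.atleast_2d(np.asarray(self.input_values, dtype=float))

    @property
    def is_point_process(self) -> bool:
        return self.events is not None

    def inputs_at(self, times: np.ndarray) -> np.ndarray | None:
        """Piecewise-constant (left-hold) input signal evaluated at ``times``."""
        if self.input_times is None:
            return None
        idx = np.clip(
            np.searchsorted(self.input_times, times, side="right") - 1,
            0,
            len(self.input_times) - 1,
        )
        return self.input_values[idx]


def simulate_latent_path(
    model: GPSLDSModel,
    drift,
    x0: np.ndarray,
    dt: float,
    duration: float,
    inputs: tuple[np.ndarray, np.ndarray] | None = None,
    seed: int | np.random.Generator = 0,
):
    """Euler-Maruyama simulation of ``dx = (f(x) + B v_t) dt + Sigma^{1/2} dw``.

    Returns ``(times, path)`` with ``times`` of length ``n_steps + 1``.
    """
    if dt <= 0 or duration < dt:
        raise ValueError("need dt > 0 and duration >= dt")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x0 = np.asarray(x0, dtype=float).ravel()
    k = x0.shape[0]
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt
    sqrt_cov = _psd_sqrt(model.noise_cov)
    noisy = np.any(model.noise_cov != 0.0)
    if inputs is not None:
        in_t = np.asarray(inputs[0], dtype=float).ravel()
        in_v = np.atleast_2d(np.asarray(inputs[1], dtype=float))
        if model.input_map is None:
            raise ValueError("model has no input_map but inputs were supplied")
    path = np.empty((n_steps + 1, k))
    path[0] = x0
    sdt = np.sqrt(dt)
    for n in range(n_steps):
        fx = np.asarray(drift(path[n]), dtype=float).ravel()
        if not np.all(np.isfinite(fx)):
            raise FloatingPointError(f"drift returned non-finite values at step {n}")
        if inputs is not None:
            idx = np.clip(np.searchsorted(in_t, times[n], side="right") - 1, 0, len(in_t) - 1)
            fx = fx + model.input_map @ in_v[idx]
        step = path[n] + fx * dt
        if noisy:
            step = step + sqrt_cov @ rng.standard_normal(k) * sdt
        path[n + 1] = step
    return times, path


def _psd_sqrt(mat: np.ndarray) -> np.ndarray:
    mat = np.atleast_2d(np.asarray(mat, dtype=float))
    if np.allclose(mat, np.diag(np.diag(mat))):
        return np.diag(np.sqrt(np.maximum(np.diag(mat), 0.0)))
    vals, vecs = np.linalg.eigh(0.5 * (mat + mat.T))
    return vecs @ np.diag(np.sqrt(np.maximum(vals, 0.0))) @ vecs.T


def sample_dynamics_from_prior(params, grid: np.ndarray, seed: int = 0, n_out: int | None = None):
    """Joint GP function samples of the drift on a grid of query points.

    Each output dimension of the drift is an independent draw from the kernel's
    Gram matrix on the grid.  Returns ``(N, K)`` where by default K equals the
    dimensionality of the grid points.
    """
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    if n_out is None:
        n_out = grid.shape[1]
    kernel = make_kernel(params)
    G = kernel.gram(grid)
    # eigen-factor rather than jittered Cholesky: SSL Gram matrices are exactly
    # low rank (e.g. affine samples for J=1) and jitter noise would break that
    vals, vecs = np.linalg.eigh(0.5 * (G + G.T))
    if vals.min() < -1e-8 * max(np.trace(G), 1e-300):
        raise np.linalg.LinAlgError("Gram matrix is not PSD")
    L = vecs * np.sqrt(np.maximum(vals, 0.0))
    rng = np.random.default_rng(seed)
    return (L @ rng.standard_normal((grid.shape[0], n_out))).reshape(grid.shape[0], n_out)


def sample_poisson_process_observations(
    times: np.ndarray,
    path: np.ndarray,
    model: GPSLDSModel,
    seed: int | np.random.Generator = 0,
    inputs: tuple[np.ndarray, np.ndarray] | None = None,
    trial_id: int = 0,
) -> TrialData:
    """Poisson-process event times from a latent path, by thinning.

    Within each simulation step the log-intensity is linearly interpolated and
    candidate events drawn at the per-step bound ``max(lambda_n, lambda_{n+1})``
    are accepted with probability ``lambda(t) / bound`` (Lewis-Shedler
    thinning), which preserves continuous event times.
    """
    if model.link_id != "exp":
        raise ValueError("point-process sampling requires the exponential link")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    times = np.asarray(times, dtype=float).ravel()
    log_rate = path @ model.obs_map.T + model.obs_offset  # (N, D)
    if np.any(log_rate > np.log(MAX_INTENSITY_HZ)):
        raise FloatingPointError(
            "intensity exceeds 1e6 Hz; rescale the observation map C or offset d"
        )
    rate = np.exp(log_rate)
    events: list[np.ndarray] = []
    dt_steps = np.diff(times)
    for d in range(model.D):
        bounds = np.maximum(rate[:-1, d], rate[1:, d])
        counts = rng.poisson(bounds * dt_steps)
        ev = []
        for n in np.nonzero(counts)[0]:
            lo, hi = times[n], times[n + 1]
            t_cand = rng.uniform(lo, hi, size=counts[n])
            frac = (t_cand - lo) / (hi - lo)
            lam = np.exp((1 - frac) * log_rate[n, d] + frac * log_rate[n + 1, d])
            accept = rng.uniform(0.0, 1.0, size=counts[n]) < lam / bounds[n]
            ev.append(t_cand[accept])
        events.append(np.sort(np.concatenate(ev)) if ev else np.empty(0))
    inp_t, inp_v = (inputs if inputs is not None else (None, None))
    return TrialData(
        duration=float(times[-1]),
        events=events,
        input_times=inp_t,
        input_values=inp_v,
        trial_id=trial_id,
    )


def sample_gaussian_observations(
    times: np.ndarray,
    path: np.ndarray,
    model: GPSLDSModel,
    sample_times: np.ndarray,
    seed: int | np.random.Generator = 0,
    inputs: tuple[np.ndarray, np.ndarray] | None = None,
    trial_id: int = 0,
) -> TrialData:
    """Gaussian observations ``y ~ N(C x(t_i) + d, diag(obs_noise_var))``."""
    if model.link_id != "identity":
        raise ValueError("Gaussian sampling requires the identity link")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    times = np.asarray(times, dtype=float).ravel()
    sample_times = np.asarray(sample_times, dtype=float).ravel()
    if sample_times.size and (
        sample_times.min() < times[0] - 1e-12 or sample_times.max() > times[-1] + 1e-12
    ):
        raise ValueError("sample_times fall outside the simulated path support")
    x_at = np.empty((sample_times.size, path.shape[1]))
    for k in range(path.shape[1]):
        x_at[:, k] = np.interp(sample_times, times, path[:, k])
    mean = x_at @ model.obs_map.T + model.obs_offset
    noise_var = (
        model.obs_noise_var
        if model.obs_noise_var is not None
        else np.zeros(model.D)
    )
    y = mean + rng.standard_normal(mean.shape) * np.sqrt(noise_var)
    inp_t, inp_v = (inputs if inputs is not None else (None, None))
    return TrialData(
        duration=float(times[-1]),
        sample_times=sample_times,
        observations=y,
        input_times=inp_t,
        input_values=inp_v,
        trial_id=trial_id,
    )
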