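"""scikit-learn style estimator facade for the gpSLDS."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import analysis as _analysis
from . import inference as _inference
from .kernels import partition_weights
from .simulate import TrialData

__all__ = ["GPSLDS"]


class GPSLDS(BaseEstimator):
    """Gaussian process switching linear dynamical system.

    A continuous-time latent SDE whose drift carries a smoothly-switching-
    linear GP prior, fitted to multi-trial point-process or Gaussian
    observations by variational EM with sparse inducing points.

    Parameters mirror :class:`gpslds.inference.FitConfig`; ``fit`` consumes a
    list of :class:`gpslds.simulate.TrialData`.  Fitted attributes follow the
    sklearn convention (``elbo_trace_``, ``kernel_params_``, ``state_`` ...).

    Examples
    --------
    >>> from gpslds.datasets import make_two_rotation_dataset
    >>> trials, truth = make_two_rotation_dataset(n_trials=2, n_outputs=5,
    ...                                           duration=0.5, seed=0)
    >>> model = GPSLDS(n_latents=2, n_regimes=2, vem_iterations=0, n_init=1)
    >>> state = model.fit(trials).state_
    """

    def __init__(
        self,
        n_latents: int = 2,
        n_regimes: int = 2,
        n_inducing: int = 36,
        kernel: str = "ssl",
        feature_map: str = "affine",
        temperature: float = 1.0,
        dt_inference: float = 5e-3,
        vem_iterations: int = 30,
        n_init: int = 5,
        quad_order: int = 6,
        m_step_maxiter: int = 8,
        qx_sweeps: int = 1,
        process_noise: float = 0.1,
        learn_sigma: bool = True,
        learn_obs: bool = True,
        learn_temperature: bool = False,
        seed: int = 0,
        verbose: bool = False,
    ):
        self.n_latents = n_latents
        self.n_regimes = n_regimes
        self.n_inducing = n_inducing
        self.kernel = kernel
        self.feature_map = feature_map
        self.temperature = temperature
        self.dt_inference = dt_inference
        self.vem_iterations = vem_iterations
        self.n_init = n_init
        self.quad_order = quad_order
        self.m_step_maxiter = m_step_maxiter
        self.qx_sweeps = qx_sweeps
        self.process_noise = process_noise
        self.learn_sigma = learn_sigma
        self.learn_obs = learn_obs
        self.learn_temperature = learn_temperature
        self.seed = seed
        self.verbose = verbose

    # ------------------------------------------------------------------
    def _config(self) -> _inference.FitConfig:
        return _inference.FitConfig(
            K=self.n_latents,
            J=self.n_regimes,
            n_inducing=self.n_inducing,
            dt_inference=self.dt_inference,
            vem_iterations=self.vem_iterations,
            n_init=self.n_init,
            seed=self.seed,
            quad_order=self.quad_order,
            qx_sweeps=self.qx_sweeps,
            m_step_maxiter=self.m_step_maxiter,
            learn_temperature=self.learn_temperature,
            learn_obs=self.learn_obs,
            learn_sigma=self.learn_sigma,
            kernel_kind=self.kernel,
            feature_map_id=self.feature_map,
            temperature=self.temperature,
            process_noise=self.process_noise,
        )

    def fit(self, X, y=None):
        """Fit to a list of trials (best ELBO over ``n_init`` restarts)."""
        if not isinstance(X, (list, tuple)) or not all(
            isinstance(t, TrialData) for t in X
        ):
            raise TypeError("X must be a list of TrialData trials")
        self.state_ = _inference.fit(list(X), self._config(), verbose=self.verbose)
        self.model_ = self.state_.model
        self.kernel_params_ = self.state_.model.kernel
        self.inducing_posterior_ = self.state_.q_u
        self.elbo_trace_ = np.asarray(self.state_.elbo_trace)
        return self

    def predict_dynamics(self, X) -> _analysis.DynamicsPosterior:
        """Posterior mean/variance of the drift at query points ``X (N, K)``."""
        self._check_fitted()
        return _analysis.predict_dynamics(self.model_, self.inducing_posterior_, X)

    def predict(self, X):
        """Posterior-mean drift at query points (alias used by sklearn tooling)."""
        return self.predict_dynamics(X).mean

    def partition(self, X):
        """Regime probabilities ``pi(x)`` at query points (SSL kernel only)."""
        self._check_fitted()
        return np.atleast_2d(partition_weights(X, self.kernel_params_))

    def fixed_point_probability(self, X, epsilon: float | None = None):
        post = self.predict_dynamics(X)
        return _analysis.fixed_point_probability(post, epsilon)

    def forward_simulation_r2(self, horizon_steps: int, spacing: int) -> float:
        self._check_fitted()
        return _analysis.forward_simulation_r2(self.state_, horizon_steps, spacing)

    def score(self, X=None, y=None) -> float:
        """Final evidence lower bound of the best restart."""
        self._check_fitted()
        return float(self.elbo_trace_[-1])

    def _check_fitted(self):
        if not hasattr(self, "state_"):
            raise AttributeError("this GPSLDS instance is not fitted yet; call fit first")
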