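import numpy as np
import pytest

from gpslds.kernels import SSLKernelParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_regime_params():
    """A generic asymmetric two-regime SSL kernel in 2D."""
    return SSLKernelParams(
        M_diag=np.array([0.7, 1.3]),
        sigma0_sq=0.3,
        centers=np.array([[2.0, 1.0], [-1.0, -2.0]]),
        boundary_weights=np.array([[0.8, -0.5, 0.2]]),
        temperature=0.7,
    )


def random_ssl_params(rng, K=2, J=2, feature_map="affine"):
    from gpslds.kernels import feature_dim

    return SSLKernelParams(
        M_diag=rng.uniform(0.1, 2.0, K),
        sigma0_sq=rng.uniform(0.05, 1.0),
        centers=rng.normal(0.0, 2.0, (J, K)),
        boundary_weights=rng.normal(0.0, 1.0, (J - 1, feature_dim(K, feature_map))),
        temperature=rng.uniform(0.3, 2.0),
        feature_map_id=feature_map,
    )
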