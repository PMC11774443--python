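"""Thin plotting helpers for flow fields and probability maps."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_flow_field", "plot_probability_map"]


def plot_flow_field(post, ax=None, color_by_regime=True, **quiver_kw):
    """Quiver plot of a posterior flow field on a 2D grid of query points."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    X, F = post.query_points, post.mean
    if X.shape[1] != 2:
        raise ValueError("flow-field plotting requires 2D latents")
    if color_by_regime and post.regime_probs is not None:
        colors = np.argmax(post.regime_probs, axis=1)
        ax.quiver(X[:, 0], X[:, 1], F[:, 0], F[:, 1], colors, **quiver_kw)
    else:
        ax.quiver(X[:, 0], X[:, 1], F[:, 0], F[:, 1], **quiver_kw)
    ax.set_xlabel("$x_1$")
    ax.set_ylabel("$x_2$")
    return ax


def plot_probability_map(points, values, ax=None, **scatter_kw):
    """Scatter map of per-point probabilities (e.g. fixed-point probability)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sc = ax.scatter(points[:, 0], points[:, 1], c=values, vmin=0.0, vmax=1.0,
                    **scatter_kw)
    plt.colorbar(sc, ax=ax)
    return ax
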