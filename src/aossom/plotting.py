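"""Simple report figures: search surfaces, selection curves, scatter plots.

Each function accepts an optional matplotlib Axes and returns the Axes it
drew on, so figures compose the usual way.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "plot_response_curves",
    "plot_search_surface",
    "plot_factor_selection",
    "plot_predictions",
]


def _ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_response_curves(recording, ax=None):
    """All ten channels of one recording against time."""
    ax = _ax(ax)
    for k, channel in enumerate(recording.channels, start=1):
        ax.plot(recording.time, channel, label=f"S{k}", linewidth=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("output voltage (V)")
    ax.set_title(recording.sample_id)
    ax.legend(ncol=2, fontsize="x-small")
    return ax


def plot_search_surface(surface: pd.DataFrame, ax=None, levels=20):
    """MSECV contour over the (log2 C, log2 sigma^2) grid."""
    ax = _ax(ax)
    log2c = surface.index.to_numpy(dtype=float)
    log2s = surface.columns.to_numpy(dtype=float)
    cs = ax.contour(log2s, log2c, np.log10(surface.to_numpy()),
                    levels=levels)
    ax.clabel(cs, inline=True, fontsize="x-small", fmt="%.1f")
    ax.set_xlabel(r"$\log_2 \sigma^2$")
    ax.set_ylabel(r"$\log_2 C$")
    ax.set_title("log10 MSECV")
    return ax


def plot_factor_selection(curve: pd.DataFrame, ax=None):
    """RMSECV and AIC against the latent-factor count, twin axes."""
    ax = _ax(ax)
    ax.plot(curve["p"], curve["rmsecv"], "o-", label="RMSECV")
    ax.set_xlabel("latent factors")
    ax.set_ylabel("RMSECV (g/kg)")
    if "aic" in curve.columns:
        twin = ax.twinx()
        twin.plot(curve["p"], curve["aic"], "s--", color="C1", label="AIC")
        twin.set_ylabel("AIC")
    return ax


def plot_predictions(pred, obs, ax=None, label=None):
    """Predicted vs observed SOM with the 1:1 line."""
    ax = _ax(ax)
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    ax.scatter(obs, pred, s=18, label=label)
    lo = min(obs.min(), pred.min())
    hi = max(obs.max(), pred.max())
    ax.plot([lo, hi], [lo, hi], "k--", linewidth=0.8)
    ax.set_xlabel("observed SOM (g/kg)")
    ax.set_ylabel("predicted SOM (g/kg)")
    if label:
        ax.legend()
    return ax
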