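"""Regime plots: data, per-regime predictive mean and 68% CPI band."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .segmentation import Segmentation
from .series import TimeSeries

__all__ = ["plot_regimes", "plot_lambda_sweep"]

_BAND_COLORS = ("0.82", "0.68")


def plot_regimes(
    series: TimeSeries,
    seg: Segmentation,
    ax: "plt.Axes | None" = None,
    title: str | None = None,
):
    """Plot a series with its regimes.

    Each regime gets a shaded band spanning the 68% central probability
    interval of its posterior predictive distribution (so the band widens
    with either mean or variance uncertainty) and a horizontal line at the
    predictive mean; alternating shades distinguish adjacent regimes.
    Returns the matplotlib figure.
    """
    if ax is None:
        fig, ax = plt.subplots(figsize=(8, 3.2))
    else:
        fig = ax.figure
    for i, reg in enumerate(seg.regimes):
        x0, x1 = reg.start - 0.5, reg.end + 0.5
        lo, hi = reg.cpi68
        ax.fill_between(
            [x0, x1], [lo, lo], [hi, hi],
            color=_BAND_COLORS[i % 2], zorder=1,
        )
        ax.hlines(reg.post_mean_mu, x0, x1, color="0.2", lw=1.4, zorder=2)
    ax.plot(series.times, series.values, "o-", ms=3, lw=0.8, color="C0", zorder=3)
    ax.set_xlabel("time")
    ax.set_ylabel(series.units or series.label or "value")
    if title is None:
        title = series.label
    if title:
        ax.set_title(title, fontsize=10)
    return fig


def plot_lambda_sweep(
    series: TimeSeries,
    segmentations: dict[float, Segmentation],
    out_path: str | Path | None = None,
):
    """One panel per hazard rate, as in the study's sensitivity figures."""
    lams = sorted(segmentations)
    fig, axes = plt.subplots(
        len(lams), 1, figsize=(8, 2.6 * len(lams)), sharex=True, squeeze=False
    )
    for ax, lam in zip(axes[:, 0], lams):
        plot_regimes(series, segmentations[lam], ax=ax, title=f"lambda = {lam:g}")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    return fig
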