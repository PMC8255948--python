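"""Plotting helpers for the comparison experiment outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_mse_curves(mse_df, ax=None):
    """Mean GCT MSE (dB) versus iteration, one curve per method."""
    if ax is None:
        _, ax = plt.subplots()
    mean = mse_df.groupby(["method", "iteration"])["mse_db"].mean()
    for method in mse_df["method"].unique():
        curve = mean.loc[method]
        ax.plot(curve.index, curve.values, marker="o", label=method)
    ax.set_xlabel("iteration")
    ax.set_ylabel("GCT MSE (dB)")
    ax.legend()
    return ax


def plot_bias_sd(roi_df, region: str, ax=None):
    """Bias versus SD trade-off traced over iterations, per method."""
    if ax is None:
        _, ax = plt.subplots()
    sel = roi_df[roi_df["region"] == region].sort_values("iteration")
    for method in sel["method"].unique():
        curve = sel[sel["method"] == method]
        ax.plot(curve["sd"], curve["bias"], marker="o", label=method)
    ax.set_xlabel("ensemble SD (relative)")
    ax.set_ylabel("ensemble bias (relative)")
    ax.set_title(f"{region} ROI")
    ax.legend()
    return ax
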