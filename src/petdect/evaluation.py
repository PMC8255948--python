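"""Evaluation metrics: image MSE in dB and ensemble bias / standard deviation.

MSE is the relative squared error in decibels,
``10 log10(||est - truth||^2 / ||truth||^2)``, over all pixels.  Ensemble
metrics summarize N_r independent noise realizations: the ROI variant uses
the ROI mean of each realization; the pixel variant applies the same formulas
per pixel (normalized by the pixel's true value) and averages over a region,
reported in percent.  SD uses the unbiased (N_r - 1) variance estimate.
"""

from __future__ import annotations

import warnings

import numpy as np


class PerfectReconstructionError(ValueError):
    """Raised when est == truth exactly, where the dB error is -infinity."""


def mse_db(est: np.ndarray, truth: np.ndarray) -> float:
    """Relative mean squared error in dB: 10 log10(||est-truth||^2/||truth||^2)."""
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if est.shape != truth.shape:
        raise ValueError("images must share one grid")
    denom = float(np.sum(truth * truth))
    if denom <= 0:
        raise ValueError("truth image must be nonzero")
    num = float(np.sum((est - truth) ** 2))
    if num == 0.0:
        raise PerfectReconstructionError("estimate equals truth exactly")
    return 10.0 * np.log10(num / denom)


def _check_ensemble(realizations, truth, mask):
    realizations = [np.asarray(im, dtype=float) for im in realizations]
    truth = np.asarray(truth, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != truth.shape or any(im.shape != truth.shape for im in realizations):
        raise ValueError("all images and the mask must share one grid")
    if not mask.any():
        raise ValueError("mask is empty")
    return realizations, truth, mask


def roi_bias_sd(realizations, truth: np.ndarray, roi: np.ndarray):
    """Ensemble bias and SD of the ROI mean, normalized by the true ROI mean.

    bias = |mean_i(c_i) - c_true| / c_true,
    sd   = sqrt(sum_i (c_i - cbar)^2 / (N_r - 1)) / c_true,
    with c_i the ROI mean of realization i.
    """
    realizations, truth, roi = _check_ensemble(realizations, truth, roi)
    c_true = truth[roi].mean()
    if c_true <= 0:
        raise ValueError("true ROI mean must be positive")
    c = np.array([im[roi].mean() for im in realizations])
    bias = abs(c.mean() - c_true) / c_true
    sd = 0.0
    if c.size > 1:
        sd = np.sqrt(np.sum((c - c.mean()) ** 2) / (c.size - 1)) / c_true
    return float(bias), float(sd)


def pixel_bias_sd(realizations, truth: np.ndarray, region: np.ndarray):
    """Pixel-based ensemble bias and SD averaged over a region, in percent.

    The ROI formulas are applied per pixel with c_true the pixel's true
    value; pixels with nonpositive truth are excluded with a warning.
    """
    realizations, truth, region = _check_ensemble(realizations, truth, region)
    usable = region & (truth > 0)
    if usable.sum() < region.sum():
        warnings.warn(
            f"excluding {int(region.sum() - usable.sum())} region pixels with "
            "nonpositive truth", RuntimeWarning,
        )
    if not usable.any():
        raise ValueError("no region pixel has positive truth")
    stack = np.stack([im[usable] for im in realizations])  # (N_r, n_pix)
    c_true = truth[usable]
    cbar = stack.mean(axis=0)
    bias = np.abs(cbar - c_true) / c_true
    if stack.shape[0] > 1:
        sd = np.sqrt(np.sum((stack - cbar) ** 2, axis=0) / (stack.shape[0] - 1)) / c_true
    else:
        sd = np.zeros_like(cbar)
    return float(bias.mean() * 100.0), float(sd.mean() * 100.0)
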