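"""Poisson TOF-PET emission model: expectations, likelihood and scan simulation.

Sinograms are dense ``(N_d, n_tof)`` arrays indexed by (detector pair, TOF
bin).  Measured counts ``y`` are independent Poisson with expectation

    ybar_m = n_m(mu) * (G_m @ lam) + r_m,

where ``n_m(mu) = c * exp(-A @ mu)`` carries the attenuation of the 511 keV
annihilation photons and ``r`` is a uniform random/scatter background.
"""

from __future__ import annotations

import numpy as np

from .phantom import PhantomSet
from .projector import SystemMatrices, build_system, test_scale_geometry


def attenuation_factors(mu: np.ndarray, sys: SystemMatrices) -> np.ndarray:
    """Survival factors n_{i,m} = c * exp(-[A mu]_i), shape (N_d, n_tof)."""
    mu = np.ravel(mu)
    if np.any(mu < 0):
        raise ValueError("attenuation image must be nonnegative")
    n_line = sys.c * np.exp(-(sys.A @ mu))
    return np.repeat(n_line[:, None], sys.geometry.n_tof, axis=1)


def expected_counts(lam: np.ndarray, mu: np.ndarray, r: np.ndarray,
                    sys: SystemMatrices) -> np.ndarray:
    """Expected TOF sinogram ybar = n(mu) * (G lam) + r."""
    n = attenuation_factors(mu, sys)
    proj = sys.tof_project(lam)
    r = np.broadcast_to(np.asarray(r, dtype=float), proj.shape)
    if proj.shape != n.shape:
        raise ValueError("sinogram shape mismatch")
    return n * proj + r


def poisson_loglik(y: np.ndarray, ybar: np.ndarray) -> float:
    """Poisson log-likelihood sum(y log ybar - ybar), with 0 log 0 := 0."""
    y = np.asarray(y, dtype=float)
    ybar = np.asarray(ybar, dtype=float)
    if y.shape != ybar.shape:
        raise ValueError("sinogram shape mismatch")
    if np.any((ybar <= 0) & (y > 0)):
        raise ValueError("zero expectation with observed counts is impossible")
    pos = ybar > 0
    return float(np.sum(y[pos] * np.log(ybar[pos]) - ybar[pos]))


def log_likelihood(y: np.ndarray, lam: np.ndarray, mu: np.ndarray,
                   r: np.ndarray, sys: SystemMatrices) -> float:
    """Log-likelihood of counts ``y`` under activity ``lam`` and attenuation ``mu``."""
    if np.any(np.asarray(y) < 0):
        raise ValueError("counts must be nonnegative")
    return poisson_loglik(y, expected_counts(lam, mu, r, sys))


def simulate_scan(phantom: PhantomSet, total_events: float = 5e6,
                  background_fraction: float = 0.4, seed: int = 0,
                  sys: SystemMatrices | None = None):
    """Simulate one noisy TOF scan of the phantom.

    The activity is rescaled so the expected prompts total ``total_events``,
    of which ``background_fraction`` is a uniform random/scatter background:
    sum(r) = background_fraction * sum(ybar).

    Returns
    -------
    y : ndarray (N_d, n_tof)
        Poisson counts.
    r : ndarray (N_d, n_tof)
        Uniform background expectation included in the model.
    scale : float
        Factor applied to the phantom activity.
    sys : SystemMatrices
        The system used (built at test scale if not supplied).
    """
    if total_events <= 0:
        raise ValueError("total_events must be positive")
    if not 0 <= background_fraction < 1:
        raise ValueError("background_fraction must be in [0, 1)")
    if sys is None:
        sys = build_system(phantom.grid, test_scale_geometry(phantom.grid))

    n = attenuation_factors(phantom.mu511, sys)
    trues_unit = n * sys.tof_project(phantom.activity)
    total_trues_unit = trues_unit.sum()
    if total_trues_unit <= 0:
        raise ValueError("phantom produces no expected events")

    target_trues = (1.0 - background_fraction) * total_events
    scale = target_trues / total_trues_unit
    r_value = background_fraction * total_events / trues_unit.size
    r = np.full(trues_unit.shape, r_value)
    ybar = scale * trues_unit + r

    rng = np.random.default_rng(seed)
    y = rng.poisson(ybar).astype(float)
    return y, r, scale, sys
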