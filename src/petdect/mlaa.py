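"""Joint activity/attenuation estimation (MLAA) and its kernelized variant.

Standard MLAA alternates a multiplicative MLEM update of the activity image
``lam`` (attenuation fixed) with a separable-paraboloidal-surrogate (SPS)
ascent step on the attenuation image ``mu`` (activity fixed), maximizing the
Poisson log-likelihood of the TOF sinogram.  Kernel MLAA represents
``mu = K @ alpha`` with a row-stochastic similarity matrix K built from an
anatomical prior and performs the SPS step on the coefficient image ``alpha``.

The SPS step uses the precomputed curvature d_j = [A^T (gamma * sum_m t_m)]_j
with gamma_i the ray length through the image; because that surrogate is not
guaranteed monotone in the presence of a background term, each attenuation
step carries a step-halving safeguard (up to ``max_halvings`` halvings, then
revert), so every recorded log-likelihood value is non-decreasing.

Estimators follow the scikit-learn protocol: ``fit`` consumes the measured
sinogram and exposes ``lam_``, ``mu_`` (and ``alpha_``), plus a per-half-step
``loglik_trace_``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix, identity
from sklearn.base import BaseEstimator

from .forward_model import attenuation_factors, poisson_loglik
from .kernels import SparseKernelMatrix
from .projector import SystemMatrices

_EPS = 1e-300


@dataclass
class ReconState:
    """Snapshot of a (kernel) MLAA reconstruction."""

    lam: np.ndarray
    mu: np.ndarray
    alpha: np.ndarray | None
    iteration: int
    loglik_trace: list = field(default_factory=list)


def _nonneg_lstsq(K: csr_matrix, b: np.ndarray, n_iter: int = 200) -> np.ndarray:
    """Nonnegative least squares min ||K x - b||, x >= 0, by multiplicative
    (image-space restoration) iterations; monotone and sign-safe."""
    Ktb = K.T @ b
    x = b.copy()
    for _ in range(n_iter):
        denom = K.T @ (K @ x)
        good = denom > 0
        x[good] *= Ktb[good] / denom[good]
        x[~good] = 0.0
    return x


def _as_sparse(kernel) -> csr_matrix:
    if isinstance(kernel, SparseKernelMatrix):
        return kernel.K
    return csr_matrix(kernel)


def _check_ybar(y: np.ndarray, ybar: np.ndarray) -> None:
    if np.any((ybar <= 0) & (y > 0)):
        raise ValueError("zero expected counts where data are observed")


def mlem_lambda_update(lam: np.ndarray, y: np.ndarray, r: np.ndarray,
                       n: np.ndarray, sys: SystemMatrices) -> np.ndarray:
    """One MLEM step on the activity with attenuation factors ``n`` fixed.

    lam_j <- (lam_j / s_j) * sum_{i,m} n_im G_m,ij y_im / ybar_im with
    sensitivity s_j = sum_{i,m} n_im G_m,ij; pixels with s_j = 0 are frozen.
    """
    lam = np.ravel(np.asarray(lam, dtype=float))
    proj = sys.tof_project(lam)
    ybar = n * proj + r
    _check_ybar(y, ybar)
    ratio = np.divide(y, ybar, out=np.zeros_like(ybar), where=ybar > 0)
    back = sys.tof_backproject(n * ratio)
    s = sys.tof_backproject(n)
    out = lam.copy()
    active = s > 0
    out[active] = lam[active] * back[active] / s[active]
    return out


def _sps_direction(t: np.ndarray, ratio: np.ndarray, gamma: np.ndarray,
                   sys: SystemMatrices):
    """Gradient and SPS curvature of the likelihood w.r.t. mu.

    g_j = dL/dmu_j = [A^T sum_m t_m (1 - y/ybar)]_j
    d_j = [A^T (gamma * sum_m t_m)]_j
    """
    q = (t * (1.0 - ratio)).sum(axis=1)
    g = sys.A.T @ q
    d = sys.A.T @ (gamma * t.sum(axis=1))
    return g, d


def _safe_step(g: np.ndarray, d: np.ndarray) -> np.ndarray:
    bad = (d <= 0) & (g != 0)
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} pixels have zero SPS curvature with nonzero "
            "gradient; leaving them unchanged", RuntimeWarning,
        )
    return np.divide(g, d, out=np.zeros_like(g), where=d > 0)


def sps_mu_update(mu: np.ndarray, y: np.ndarray, r: np.ndarray,
                  lam: np.ndarray, sys: SystemMatrices,
                  max_halvings: int = 10) -> np.ndarray:
    """One safeguarded SPS ascent step on the attenuation image.

    mu_j <- max(0, mu_j + g_j / d_j), halving the step (up to ``max_halvings``
    times, then reverting) whenever the log-likelihood would decrease.
    """
    mu = np.ravel(np.asarray(mu, dtype=float))
    lam = np.ravel(np.asarray(lam, dtype=float))
    proj = sys.tof_project(lam)
    n = attenuation_factors(mu, sys)
    t = n * proj
    ybar = t + r
    _check_ybar(y, ybar)
    ratio = np.divide(y, ybar, out=np.zeros_like(ybar), where=ybar > 0)
    gamma = np.asarray(sys.A.sum(axis=1)).ravel()
    g, d = _sps_direction(t, ratio, gamma, sys)
    delta = _safe_step(g, d)

    loglik_before = poisson_loglik(y, ybar)
    step = 1.0
    for _ in range(max_halvings + 1):
        cand = np.maximum(0.0, mu + step * delta)
        ybar_cand = attenuation_factors(cand, sys) * proj + r
        if poisson_loglik(y, ybar_cand) >= loglik_before:
            return cand
        step *= 0.5
    return mu


def kernel_sps_alpha_update(alpha: np.ndarray, y: np.ndarray, r: np.ndarray,
                            lam: np.ndarray, kernel, sys: SystemMatrices,
                            max_halvings: int = 10) -> np.ndarray:
    """Safeguarded SPS step on the kernel coefficients with mu = K alpha.

    The gradient is pulled back through K (g_alpha = K^T g_mu); the curvature
    uses the row-stochasticity of K, so with K = I this reduces exactly to
    :func:`sps_mu_update`.
    """
    K = _as_sparse(kernel)
    alpha = np.ravel(np.asarray(alpha, dtype=float))
    lam = np.ravel(np.asarray(lam, dtype=float))
    mu = K @ alpha
    proj = sys.tof_project(lam)
    n = attenuation_factors(mu, sys)
    t = n * proj
    ybar = t + r
    _check_ybar(y, ybar)
    ratio = np.divide(y, ybar, out=np.zeros_like(ybar), where=ybar > 0)
    gamma = np.asarray(sys.A.sum(axis=1)).ravel()
    g_mu, d_mu = _sps_direction(t, ratio, gamma, sys)
    g = K.T @ g_mu
    d = K.T @ d_mu
    delta = _safe_step(g, d)

    loglik_before = poisson_loglik(y, ybar)
    step = 1.0
    for _ in range(max_halvings + 1):
        cand = np.maximum(0.0, alpha + step * delta)
        ybar_cand = attenuation_factors(K @ cand, sys) * proj + r
        if poisson_loglik(y, ybar_cand) >= loglik_before:
            return cand
        step *= 0.5
    return alpha


class MLAA(BaseEstimator):
    """Standard MLAA reconstructor (interleaved MLEM / safeguarded SPS).

    Parameters
    ----------
    sys : SystemMatrices
        Forward model operators.
    n_outer : int
        Outer iterations; each runs ``inner_lam`` MLEM steps then ``inner_mu``
        SPS steps.
    inner_lam, inner_mu : int
        Inner iterations per outer iteration.
    max_halvings : int
        Step-halving budget of the attenuation safeguard.

    Attributes
    ----------
    lam_ : ndarray
        Estimated activity image (flattened).
    mu_ : ndarray
        Estimated 511 keV attenuation image (flattened).
    loglik_trace_ : list of float
        Log-likelihood recorded after every inner update.
    snapshots_ : dict
        ``{outer_iteration: mu copy}`` for requested snapshot iterations.
    """

    def __init__(self, sys: SystemMatrices = None, n_outer: int = 600,
                 inner_lam: int = 1, inner_mu: int = 1, max_halvings: int = 10):
        self.sys = sys
        self.n_outer = n_outer
        self.inner_lam = inner_lam
        self.inner_mu = inner_mu
        self.max_halvings = max_halvings

    # -- internals -----------------------------------------------------
    def _init_images(self, y, r, init_mu, init_lam):
        sys = self.sys
        n_pix = sys.grid.n_pixels
        if init_mu is None:
            init_mu = np.zeros(n_pix)
        mu = np.ravel(np.asarray(init_mu, dtype=float)).copy()
        if np.any(mu < 0):
            raise ValueError("init_mu must be nonnegative")
        if init_lam is None:
            # uniform activity matched to the estimated trues
            n = attenuation_factors(mu, sys)
            ones_proj = (n * sys.tof_project(np.ones(n_pix))).sum()
            trues = max(float(np.sum(y) - np.sum(r)), 1.0)
            init_lam = np.full(n_pix, trues / max(ones_proj, _EPS))
        lam = np.ravel(np.asarray(init_lam, dtype=float)).copy()
        return lam, mu

    def _mu_step(self, lam, mu, aux, y, r, proj):
        """One attenuation half-step; returns (mu, aux, loglik). aux unused here."""
        mu = sps_mu_update(mu, y, r, lam, self.sys, self.max_halvings)
        ybar = attenuation_factors(mu, self.sys) * proj + r
        return mu, aux, poisson_loglik(y, ybar)

    # -- estimator API -------------------------------------------------
    def fit(self, y: np.ndarray, r=0.0, init_mu=None, init_lam=None,
            snapshot_iters=()):
        """Reconstruct from the measured TOF sinogram ``y``.

        Parameters
        ----------
        y : ndarray (N_d, n_tof)
            Measured counts.
        r : ndarray or float
            Background (randoms + scatter) expectation.
        init_mu : ndarray, optional
            Initial attenuation, typically the CT-converted 511 keV map.
        init_lam : ndarray, optional
            Initial activity; defaults to a count-matched uniform image.
        snapshot_iters : iterable of int
            Outer iterations at which to store a copy of ``mu``.
        """
        if self.sys is None:
            raise ValueError("sys (SystemMatrices) must be provided")
        y = np.asarray(y, dtype=float)
        if np.any(y < 0):
            raise ValueError("counts must be nonnegative")
        r = np.broadcast_to(np.asarray(r, dtype=float),
                            (self.sys.shape[0], self.sys.geometry.n_tof))
        lam, mu = self._init_images(y, r, init_mu, init_lam)
        aux = self._init_aux(mu)

        snapshot_iters = set(int(i) for i in snapshot_iters)
        self.snapshots_ = {}
        if 0 in snapshot_iters:
            self.snapshots_[0] = mu.copy()
        trace: list[float] = []
        for outer in range(1, self.n_outer + 1):
            n = attenuation_factors(mu, self.sys)
            for _ in range(self.inner_lam):
                lam = mlem_lambda_update(lam, y, r, n, self.sys)
            proj = self.sys.tof_project(lam)
            trace.append(poisson_loglik(y, n * proj + r))
            for _ in range(self.inner_mu):
                mu, aux, loglik = self._mu_step(lam, mu, aux, y, r, proj)
                trace.append(loglik)
            if outer in snapshot_iters:
                self.snapshots_[outer] = mu.copy()
        self.lam_ = lam
        self.mu_ = mu
        self.loglik_trace_ = trace
        self.n_iter_ = self.n_outer
        self._finalize(aux)
        return self

    def _init_aux(self, mu):
        return None

    def _finalize(self, aux):
        pass

    def state(self) -> ReconState:
        return ReconState(lam=self.lam_, mu=self.mu_,
                          alpha=getattr(self, "alpha_", None),
                          iteration=self.n_iter_,
                          loglik_trace=self.loglik_trace_)


class KernelMLAA(MLAA):
    """Kernel MLAA: the attenuation image is constrained to mu = K alpha.

    ``kernel`` is a :class:`~petdect.kernels.SparseKernelMatrix` (or any
    sparse row-stochastic matrix).  ``alpha`` is initialized to ``init_mu``,
    which is consistent because K is row-stochastic.  With K = I the
    reconstruction is identical to :class:`MLAA`.

    Extra attribute: ``alpha_``, with ``mu_ = K @ alpha_``.
    """

    def __init__(self, sys: SystemMatrices = None, kernel=None,
                 n_outer: int = 600, inner_lam: int = 1, inner_mu: int = 1,
                 max_halvings: int = 10):
        super().__init__(sys=sys, n_outer=n_outer, inner_lam=inner_lam,
                         inner_mu=inner_mu, max_halvings=max_halvings)
        self.kernel = kernel

    def _init_aux(self, mu):
        if self.kernel is None:
            self._K = identity(mu.size, format="csr")
        else:
            self._K = _as_sparse(self.kernel)
        # alpha^0 such that K alpha^0 ~= init_mu, so the kernel constraint does
        # not discard the CT initialization.  When K barely smooths init_mu
        # (e.g. K = I), alpha^0 = init_mu is already exact and is kept as is.
        smooth_err = np.linalg.norm(self._K @ mu - mu)
        if smooth_err <= 1e-12 * max(np.linalg.norm(mu), 1.0):
            return mu.copy()
        return _nonneg_lstsq(self._K, mu)

    def _mu_step(self, lam, mu, alpha, y, r, proj):
        alpha = kernel_sps_alpha_update(alpha, y, r, lam, self._K, self.sys,
                                        self.max_halvings)
        mu = self._K @ alpha
        ybar = attenuation_factors(mu, self.sys) * proj + r
        return mu, alpha, poisson_loglik(y, ybar)

    def _finalize(self, alpha):
        self.alpha_ = alpha


def mlaa_reconstruct(y, r, sys, init_mu=None, n_outer=600, inner_lam=1,
                     inner_mu=1, snapshot_iters=()) -> ReconState:
    """Functional wrapper around :class:`MLAA`."""
    est = MLAA(sys=sys, n_outer=n_outer, inner_lam=inner_lam, inner_mu=inner_mu)
    est.fit(y, r=r, init_mu=init_mu, snapshot_iters=snapshot_iters)
    state = est.state()
    state.snapshots = est.snapshots_
    return state


def kernel_mlaa_reconstruct(y, r, sys, kernel, init_mu=None, n_outer=600,
                            inner_lam=1, inner_mu=1, snapshot_iters=()) -> ReconState:
    """Functional wrapper around :class:`KernelMLAA`; returns mu = K alpha."""
    est = KernelMLAA(sys=sys, kernel=kernel, n_outer=n_outer,
                     inner_lam=inner_lam, inner_mu=inner_mu)
    est.fit(y, r=r, init_mu=init_mu, snapshot_iters=snapshot_iters)
    state = est.state()
    state.snapshots = est.snapshots_
    return state
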