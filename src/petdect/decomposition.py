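"""Dual-energy multi-material decomposition.

Each pixel's dual-energy pair u = (x-ray CT at 80 keV, gamma-ray CT at
511 keV) is fit by least squares to three basis materials (air, soft
tissue/water, bone) under the constraint that the fractions sum to one.
Eliminating the air fraction rho_A = 1 - rho_S - rho_B reduces the problem to
an unconstrained 2x2 linear system solved in closed form.  Fractions are not
clipped to [0, 1] by default, so noise can push individual fractions outside
the unit interval while the sum stays exactly one.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .materials import MaterialTable, make_material_table


def _reduced_design(U: np.ndarray):
    """2x2 design [col_S - col_A, col_B - col_A] and offset col_A."""
    U = np.asarray(U, dtype=float)
    if U.shape != (2, 3):
        raise ValueError("basis matrix must be 2x3 (energies x materials)")
    offset = U[:, 0]
    M = np.column_stack([U[:, 1] - U[:, 0], U[:, 2] - U[:, 0]])
    if abs(np.linalg.det(M)) < 1e-12 * max(1.0, np.abs(M).max() ** 2):
        raise ValueError("reduced basis design is rank deficient")
    return M, offset


def decompose_pixel(u, U: np.ndarray) -> np.ndarray:
    """Sum-constrained least-squares fractions (rho_A, rho_S, rho_B) of one pixel.

    Minimizes ||u - U rho||^2 subject to sum(rho) = 1; with a full-rank
    reduced design the 2x2 system is determined and the fit is exact.
    """
    M, offset = _reduced_design(U)
    sb = np.linalg.solve(M, np.asarray(u, dtype=float) - offset)
    return np.array([1.0 - sb.sum(), sb[0], sb[1]])


def decompose_image(xct80: np.ndarray, gct511: np.ndarray,
                    U: np.ndarray | None = None,
                    clip: bool = False) -> np.ndarray:
    """Pixel-wise material decomposition of a co-registered dual-energy pair.

    Parameters
    ----------
    xct80, gct511 : ndarray
        Low-energy (80 keV) and high-energy (511 keV) attenuation images on
        one grid.
    U : ndarray (2, 3), optional
        Basis matrix, rows = energies, columns = (air, soft, bone); defaults
        to the NIST-derived material table.
    clip : bool
        If True, clip fractions to [0, 1] and renormalize the sum to 1.

    Returns
    -------
    ndarray, shape xct80.shape + (3,)
        Fraction images (air, soft, bone); each pixel sums to 1.
    """
    xct80 = np.asarray(xct80, dtype=float)
    gct511 = np.asarray(gct511, dtype=float)
    if xct80.shape != gct511.shape:
        raise ValueError("dual-energy images must share one grid")
    if U is None:
        U = make_material_table().basis_matrix()
    M, offset = _reduced_design(U)
    rhs = np.stack([xct80 - offset[0], gct511 - offset[1]], axis=-1)
    sb = rhs @ np.linalg.inv(M).T
    fractions = np.concatenate([1.0 - sb.sum(axis=-1, keepdims=True), sb], axis=-1)
    if clip:
        fractions = np.clip(fractions, 0.0, 1.0)
        fractions /= fractions.sum(axis=-1, keepdims=True)
    return fractions


class MaterialDecomposer(BaseEstimator, TransformerMixin):
    """Scikit-learn style wrapper: transform((xct80, gct511)) -> fractions."""

    def __init__(self, table: MaterialTable | None = None, clip: bool = False):
        self.table = table
        self.clip = clip

    def fit(self, X=None, y=None):
        table = self.table if self.table is not None else make_material_table()
        self.basis_matrix_ = table.basis_matrix()
        return self

    def transform(self, X):
        if not hasattr(self, "basis_matrix_"):
            self.fit()
        xct80, gct511 = X
        return decompose_image(xct80, gct511, U=self.basis_matrix_,
                               clip=self.clip)
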