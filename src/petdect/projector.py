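"""Parallel-beam TOF system model: ray-traced emission and transmission operators.

A generic 2D parallel-beam ring stands in for a clinical TOF-PET scanner: the
transmission operator ``A`` holds exact pixel intersection lengths (Siddon ray
tracing), and each TOF emission operator ``G_m`` is the same geometric path
weighted by a Gaussian time-of-flight profile (spatial FWHM set by the timing
resolution) integrated over TOF bin ``m``.  Per-ray TOF weights sum to one
across bins, so summing the ``G_m`` recovers the non-TOF projector exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.special import erf

from .grid import ImageGrid

SPEED_OF_LIGHT_CM_PER_PS = 0.0299792458


@dataclass(frozen=True)
class ScannerGeometry:
    """2D parallel-beam geometry with TOF binning.

    Parameters
    ----------
    n_angles : int
        Projection angles uniformly covering 180 degrees.
    n_radial : int
        Radial (detector-pair offset) samples per angle.
    radial_spacing : float
        Radial sample spacing in cm.
    n_tof : int
        Number of TOF bins; odd so one bin is centered on the scanner axis.
    tof_fwhm : float
        Spatial FWHM (cm) of the TOF localization kernel.
    tof_bin_width : float
        Width (cm) of one TOF bin along the line of response.
    """

    n_angles: int
    n_radial: int
    radial_spacing: float
    n_tof: int
    tof_fwhm: float
    tof_bin_width: float

    def __post_init__(self) -> None:
        if self.n_angles < 1 or self.n_radial < 1:
            raise ValueError("geometry must have at least one angle and radial bin")
        if self.n_tof < 1 or self.n_tof % 2 == 0:
            raise ValueError("n_tof must be odd and >= 1")
        if self.tof_fwhm <= 0 or self.tof_bin_width <= 0 or self.radial_spacing <= 0:
            raise ValueError("spacings and TOF FWHM must be positive")

    @property
    def n_detectors(self) -> int:
        return self.n_angles * self.n_radial


def tof_fwhm_from_timing(timing_resolution_ps: float = 550.0) -> float:
    """Spatial TOF FWHM (cm) from coincidence timing resolution (ps).

    The factor 1/2 converts the photon path-length difference to a position
    along the line of response.
    """
    return SPEED_OF_LIGHT_CM_PER_PS * timing_resolution_ps / 2.0


def default_geometry(grid: ImageGrid, n_angles: int = 180, n_radial: int = 200,
                     n_tof: int = 11, timing_resolution_ps: float = 550.0) -> ScannerGeometry:
    """Geometry defaults: radial spacing = pixel size, TOF bins spanning the FOV."""
    fov = max(grid.fov)
    return ScannerGeometry(
        n_angles=n_angles,
        n_radial=n_radial,
        radial_spacing=grid.pixel_size,
        n_tof=n_tof,
        tof_fwhm=tof_fwhm_from_timing(timing_resolution_ps),
        tof_bin_width=fov / n_tof,
    )


def test_scale_geometry(grid: ImageGrid, n_tof: int = 5) -> ScannerGeometry:
    """Reduced desk-scale geometry for fast experiments."""
    return default_geometry(grid, n_angles=60, n_radial=96, n_tof=n_tof)


@dataclass
class SystemMatrices:
    """Sparse transmission operator A and TOF emission operators G_m.

    ``A`` is (N_d, N_p) with intersection lengths in cm; ``G`` is a list of
    ``n_tof`` operators of the same shape whose sum equals ``A`` scaled by the
    detection weighting (here identity, so sum(G) == A).  ``c`` holds the
    multiplicative detector factors excluding attenuation (default 1).
    """

    A: csr_matrix
    G: list
    grid: ImageGrid
    geometry: ScannerGeometry
    c: float = 1.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.A.shape

    def project(self, image: np.ndarray) -> np.ndarray:
        """Non-TOF line integrals A @ image (flattened row-major)."""
        return self.A @ np.ravel(image)

    def tof_project(self, image: np.ndarray) -> np.ndarray:
        """TOF forward projection, shape (N_d, n_tof)."""
        x = np.ravel(image)
        return np.stack([g @ x for g in self.G], axis=1)

    def tof_backproject(self, sino: np.ndarray) -> np.ndarray:
        """Adjoint of tof_project for a (N_d, n_tof) sinogram, flattened image out."""
        out = np.zeros(self.grid.n_pixels)
        for m, g in enumerate(self.G):
            out += g.T @ sino[:, m]
        return out


def _trace_ray(origin: np.ndarray, direction: np.ndarray, grid: ImageGrid):
    """Siddon trace of one ray; returns (pixel indices, lengths, tof positions).

    The ray is parameterized p(t) = origin + t * direction with ``origin`` the
    closest point to the iso-center, so t is the signed TOF coordinate.
    """
    px = grid.pixel_size
    half_w = grid.n_cols * px / 2.0
    half_h = grid.n_rows * px / 2.0
    ox, oy = origin
    dx, dy = direction

    tmin, tmax = -np.inf, np.inf
    for o, d, lo, hi in ((ox, dx, -half_w, half_w), (oy, dy, -half_h, half_h)):
        if abs(d) < 1e-12:
            if o <= lo or o >= hi:
                return None
        else:
            t1, t2 = (lo - o) / d, (hi - o) / d
            tmin = max(tmin, min(t1, t2))
            tmax = min(tmax, max(t1, t2))
    if tmax <= tmin:
        return None

    crossings = [np.array([tmin, tmax])]
    if abs(dx) > 1e-12:
        tx = (np.arange(grid.n_cols + 1) * px - half_w - ox) / dx
        crossings.append(tx[(tx > tmin) & (tx < tmax)])
    if abs(dy) > 1e-12:
        ty = (np.arange(grid.n_rows + 1) * px - half_h - oy) / dy
        crossings.append(ty[(ty > tmin) & (ty < tmax)])
    ts = np.unique(np.concatenate(crossings))
    lengths = np.diff(ts)
    mids = 0.5 * (ts[1:] + ts[:-1])
    keep = lengths > 1e-12 * px
    lengths, mids = lengths[keep], mids[keep]
    if lengths.size == 0:
        return None

    xs = ox + mids * dx
    ys = oy + mids * dy
    cols = np.floor((xs + half_w) / px).astype(np.int64)
    rows = np.floor((ys + half_h) / px).astype(np.int64)
    ok = (cols >= 0) & (cols < grid.n_cols) & (rows >= 0) & (rows < grid.n_rows)
    pix = rows[ok] * grid.n_cols + cols[ok]
    return pix, lengths[ok], mids[ok]


def _tof_weights(tpos: np.ndarray, geom: ScannerGeometry) -> np.ndarray:
    """Per-bin TOF weights for positions ``tpos``; rows sum to 1 exactly.

    Gaussian profile integrated over each bin; the outer bins are open-ended so
    no probability mass (hence no counts) is lost off the TOF axis.
    """
    sigma = geom.tof_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    centers = (np.arange(geom.n_tof) - (geom.n_tof - 1) / 2.0) * geom.tof_bin_width
    edges = np.concatenate([
        [-np.inf], 0.5 * (centers[1:] + centers[:-1]), [np.inf],
    ]) if geom.n_tof > 1 else np.array([-np.inf, np.inf])
    z = (edges[None, :] - tpos[:, None]) / (sigma * np.sqrt(2.0))
    cdf = np.empty_like(z)
    finite = np.isfinite(z)
    cdf[finite] = 0.5 * (1.0 + erf(z[finite]))
    cdf[~finite] = np.where(z[~finite] > 0, 1.0, 0.0)
    w = np.diff(cdf, axis=1)
    w /= w.sum(axis=1, keepdims=True)
    return w


def build_system(grid: ImageGrid, geom: ScannerGeometry) -> SystemMatrices:
    """Ray-trace the transmission operator A and the TOF operators G_m.

    Rays are indexed i = angle * n_radial + radial; angles sample [0, 180)
    degrees uniformly; radial offsets are centered on the iso-center.
    """
    rows_all, cols_all, len_all, tof_all = [], [], [], []
    offsets = (np.arange(geom.n_radial) - (geom.n_radial - 1) / 2.0) * geom.radial_spacing
    for a in range(geom.n_angles):
        theta = np.pi * a / geom.n_angles
        d = np.array([np.cos(theta), np.sin(theta)])
        normal = np.array([-np.sin(theta), np.cos(theta)])
        for k, s in enumerate(offsets):
            traced = _trace_ray(s * normal, d, grid)
            if traced is None:
                continue
            pix, lengths, mids = traced
            i = a * geom.n_radial + k
            rows_all.append(np.full(pix.size, i, dtype=np.int64))
            cols_all.append(pix)
            len_all.append(lengths)
            tof_all.append(mids)

    if not rows_all:
        raise ValueError("no ray intersects the image grid")
    rows = np.concatenate(rows_all)
    cols = np.concatenate(cols_all)
    lengths = np.concatenate(len_all)
    tpos = np.concatenate(tof_all)

    shape = (geom.n_detectors, grid.n_pixels)
    A = csr_matrix((lengths, (rows, cols)), shape=shape)
    weights = _tof_weights(tpos, geom)
    G = []
    for m in range(geom.n_tof):
        vals = lengths * weights[:, m]
        keep = vals > 1e-14
        G.append(csr_matrix((vals[keep], (rows[keep], cols[keep])), shape=shape))
    return SystemMatrices(A=A, G=G, grid=grid, geometry=geom)
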