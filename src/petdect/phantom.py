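"""Procedural 2D chest phantom for PET-enabled dual-energy CT simulation.

The phantom is an ellipse-composed chest slice: a body outline, two lungs, a
liver, a spine bone and one or more hot lesions.  Every pixel carries a
material-fraction triple (air, soft tissue, bone) summing to one; the 511 keV
attenuation map and the 80 keV X-ray CT are computed exactly from those
fractions and the basis material table, so noise-free dual-energy
decomposition round-trips the fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import ImageGrid
from .materials import MaterialTable, make_material_table

DEFAULT_GRID = ImageGrid(180, 180, 0.35)

# relative activity levels per tissue (arbitrary units, rescaled at simulation)
ACTIVITY_LEVELS = {
    "lung": 0.5,
    "soft": 1.0,
    "liver": 1.5,
    "bone": 0.5,
    "lesion": 4.0,
}

# soft-tissue fraction of inflated lung; remainder is air
LUNG_SOFT_FRACTION = 0.3


@dataclass(frozen=True)
class PhantomSet:
    """Ground-truth images of one synthetic chest slice on a shared grid.

    Attributes
    ----------
    activity : ndarray
        True emission activity (relative Bq/cc), >= 0.
    mu511 : ndarray
        True 511 keV attenuation (cm^-1).
    xct80 : ndarray
        X-ray CT attenuation at 80 keV (cm^-1), the anatomical prior.
    fractions : ndarray, shape (n_rows, n_cols, 3)
        Per-pixel (air, soft, bone) material fractions, each row summing to 1.
    roi_liver, roi_bone : ndarray of bool
        Quantification ROIs fully inside the liver and the spine bone.
    """

    activity: np.ndarray
    mu511: np.ndarray
    xct80: np.ndarray
    fractions: np.ndarray
    roi_liver: np.ndarray
    roi_bone: np.ndarray
    grid: ImageGrid
    table: MaterialTable

    def __post_init__(self) -> None:
        shape = self.grid.shape
        for name in ("activity", "mu511", "xct80", "roi_liver", "roi_bone"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} does not match grid shape {shape}")
        if self.fractions.shape != shape + (3,):
            raise ValueError("fractions must have shape (n_rows, n_cols, 3)")
        sums = self.fractions.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError("material fractions must sum to 1 at every pixel")
        if np.any(self.fractions < -1e-15) or np.any(self.fractions > 1 + 1e-15):
            raise ValueError("material fractions must lie in [0, 1]")
        if np.any(self.mu511 < 0) or np.any(self.xct80 < 0):
            raise ValueError("attenuation images must be nonnegative")


def _ellipse_mask(grid: ImageGrid, center_rc: tuple[float, float],
                  semi_rc: tuple[float, float]) -> np.ndarray:
    """Boolean mask of an axis-aligned ellipse; coordinates in fractions of the grid."""
    rr, cc = np.mgrid[0:grid.n_rows, 0:grid.n_cols]
    r0 = center_rc[0] * grid.n_rows
    c0 = center_rc[1] * grid.n_cols
    ar = semi_rc[0] * grid.n_rows
    ac = semi_rc[1] * grid.n_cols
    return ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0


def _layout(grid: ImageGrid, lesion_centers) -> dict:
    """Organ masks in grid-relative coordinates on any rasterization grid."""
    body = _ellipse_mask(grid, (0.52, 0.50), (0.38, 0.44))
    lung_l = _ellipse_mask(grid, (0.42, 0.32), (0.20, 0.13))
    lung_r = _ellipse_mask(grid, (0.42, 0.68), (0.20, 0.13))
    lungs = (lung_l | lung_r) & body
    liver = _ellipse_mask(grid, (0.70, 0.38), (0.12, 0.17)) & body & ~lungs
    spine = _ellipse_mask(grid, (0.78, 0.50), (0.065, 0.055)) & body
    liver = liver & ~spine
    lesions = np.zeros(grid.shape, dtype=bool)
    for center in lesion_centers:
        lesions |= _ellipse_mask(grid, center, (0.045, 0.045)) & (lung_l | lung_r)
    return {"body": body, "lungs": lungs, "liver": liver, "spine": spine,
            "lesions": lesions}


SUPERSAMPLE = 4  # subpixel rasterization factor for partial-volume boundaries


def make_phantom(grid: ImageGrid = DEFAULT_GRID, seed: int = 0,
                 table: MaterialTable | None = None) -> PhantomSet:
    """Generate the synthetic chest phantom set, deterministic in (grid, seed).

    Organs are rasterized on a supersampled subgrid and block-averaged, so
    boundary pixels carry realistic partial-volume material mixtures (as a
    voxelized anatomical phantom would).  The seed perturbs only the
    hot-lesion placement inside the lungs; organ layout is fixed in
    grid-relative coordinates so the anatomy scales with the grid.

    Raises
    ------
    ValueError
        If the grid is too small for the organ layout (empty ROIs).
    """
    if table is None:
        table = make_material_table()
    rng = np.random.default_rng(seed)
    lesion_centers = []
    for lung_center in ((0.42, 0.32), (0.42, 0.68)):
        jitter = rng.uniform(-0.05, 0.05, size=2)
        lesion_centers.append((lung_center[0] + jitter[0],
                               lung_center[1] + jitter[1]))

    f = SUPERSAMPLE
    fine_grid = ImageGrid(grid.n_rows * f, grid.n_cols * f, grid.pixel_size / f)
    masks = _layout(fine_grid, lesion_centers)
    body, lungs, liver = masks["body"], masks["lungs"], masks["liver"]
    spine, lesions = masks["spine"], masks["lesions"]

    fractions_fine = np.zeros(fine_grid.shape + (3,))
    fractions_fine[..., 0] = 1.0  # air everywhere outside the body
    fractions_fine[body] = (0.0, 1.0, 0.0)
    fractions_fine[lungs] = (1.0 - LUNG_SOFT_FRACTION, LUNG_SOFT_FRACTION, 0.0)
    fractions_fine[lesions] = (0.0, 1.0, 0.0)  # lesions: soft tissue, hot activity
    fractions_fine[spine] = (0.0, 0.0, 1.0)

    soft_only = body & ~lungs & ~spine & ~liver
    activity_fine = np.zeros(fine_grid.shape)
    activity_fine[lungs] = ACTIVITY_LEVELS["lung"]
    activity_fine[soft_only] = ACTIVITY_LEVELS["soft"]
    activity_fine[liver] = ACTIVITY_LEVELS["liver"]
    activity_fine[spine] = ACTIVITY_LEVELS["bone"]
    activity_fine[lesions] = ACTIVITY_LEVELS["lesion"]

    def block_mean(a: np.ndarray) -> np.ndarray:
        shape = (grid.n_rows, f, grid.n_cols, f) + a.shape[2:]
        return a.reshape(shape).mean(axis=(1, 3))

    fractions = block_mean(fractions_fine)
    fractions /= fractions.sum(axis=-1, keepdims=True)  # guard rounding drift
    activity = block_mean(activity_fine)
    mu511 = fractions @ table.vector511()
    xct80 = fractions @ table.vector80()

    # ROIs on the base grid, restricted to pixels fully inside their organ
    liver_full = block_mean(liver.astype(float)) >= 1.0
    spine_full = block_mean(spine.astype(float)) >= 1.0
    roi_liver = _ellipse_mask(grid, (0.70, 0.38), (0.06, 0.09)) & liver_full
    roi_bone = _ellipse_mask(grid, (0.78, 0.50), (0.035, 0.03)) & spine_full
    if not roi_liver.any() or not roi_bone.any():
        raise ValueError(
            f"grid {grid.shape} is too small to place the organ layout; "
            "ROIs are empty"
        )

    return PhantomSet(
        activity=activity, mu511=mu511, xct80=xct80, fractions=fractions,
        roi_liver=roi_liver, roi_bone=roi_bone, grid=grid, table=table,
    )
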