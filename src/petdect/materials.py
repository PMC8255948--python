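"""Basis-material attenuation coefficients and CT energy conversion.

Linear attenuation coefficients (cm^-1) for the three basis materials used in
dual-energy decomposition: air, soft tissue (water-equivalent) and cortical
bone, at the X-ray CT energy (80 keV) and the annihilation-photon energy
(511 keV).  Values are mass attenuation coefficients from the NIST XCOM
photon cross-section database multiplied by standard densities
(air 1.205e-3 g/cc, water 1.0 g/cc, ICRU-44 cortical bone 1.92 g/cc).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MATERIALS = ("air", "soft", "bone")

# NIST XCOM mass attenuation (cm^2/g) x density (g/cc) -> cm^-1
_MU = {
    # material: (80 keV, 511 keV)
    "air": (0.1661 * 1.205e-3, 0.0870 * 1.205e-3),
    "soft": (0.1837 * 1.0, 0.0959 * 1.0),
    "bone": (0.2229 * 1.92, 0.0902 * 1.92),
}


@dataclass(frozen=True)
class MaterialTable:
    """Linear attenuation (cm^-1) of the basis materials at 80 and 511 keV."""

    mu80: dict = field(default_factory=dict)
    mu511: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for table in (self.mu80, self.mu511):
            if set(table) != set(MATERIALS):
                raise ValueError(f"material table must cover {MATERIALS}")
            if any(v < 0 for v in table.values()):
                raise ValueError("attenuation coefficients must be nonnegative")
        if not (self.mu80["bone"] > self.mu80["soft"] > self.mu80["air"]):
            raise ValueError("80 keV ordering bone > soft > air violated")
        if not self.mu80["soft"] > self.mu511["soft"]:
            raise ValueError("soft-tissue attenuation must fall from 80 to 511 keV")

    def column(self, material: str) -> np.ndarray:
        """Dual-energy column [mu80, mu511] for one material."""
        return np.array([self.mu80[material], self.mu511[material]])

    def basis_matrix(self) -> np.ndarray:
        """2x3 basis matrix, rows (80 keV, 511 keV), columns (air, soft, bone)."""
        return np.column_stack([self.column(m) for m in MATERIALS])

    def vector511(self) -> np.ndarray:
        return np.array([self.mu511[m] for m in MATERIALS])

    def vector80(self) -> np.ndarray:
        return np.array([self.mu80[m] for m in MATERIALS])


def make_material_table() -> MaterialTable:
    """Build the default air/soft-tissue/cortical-bone attenuation table."""
    return MaterialTable(
        mu80={m: _MU[m][0] for m in MATERIALS},
        mu511={m: _MU[m][1] for m in MATERIALS},
    )


def convert_ct_to_511(xct80: np.ndarray, table: MaterialTable | None = None) -> np.ndarray:
    """Convert an 80 keV X-ray CT attenuation image to 511 keV.

    Standard bilinear (piecewise-linear) conversion: below the water value the
    image is scaled by the water 511/80 ratio; above it, the excess is scaled
    by the bone-water slope between the two energies.

    Parameters
    ----------
    xct80 : ndarray
        Nonnegative attenuation image at 80 keV (cm^-1).
    table : MaterialTable, optional
        Basis coefficients; defaults to :func:`make_material_table`.
    """
    xct80 = np.asarray(xct80, dtype=float)
    if np.any(xct80 < 0):
        raise ValueError("X-ray CT attenuation must be nonnegative")
    if table is None:
        table = make_material_table()
    w80, w511 = table.mu80["soft"], table.mu511["soft"]
    b80, b511 = table.mu80["bone"], table.mu511["bone"]
    low = xct80 * (w511 / w80)
    high = w511 + (xct80 - w80) * (b511 - w511) / (b80 - w80)
    out = np.where(xct80 <= w80, low, high)
    return np.maximum(out, 0.0)
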