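"""File I/O: NIfTI images, HDF5 sinograms/kernels, JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
from scipy.sparse import csr_matrix

from .grid import ImageGrid
from .kernels import SparseKernelMatrix


def save_image(path, image: np.ndarray, pixel_size: float = 1.0) -> None:
    """Write a 2D image as a single-slice NIfTI with isotropic pixel size (cm)."""
    image = np.asarray(image, dtype=np.float64)
    affine = np.diag([pixel_size * 10.0, pixel_size * 10.0, 1.0, 1.0])  # mm
    nib.save(nib.Nifti1Image(image[:, :, None], affine), str(path))


def load_image(path) -> np.ndarray:
    """Read a 2D slice from a NIfTI file."""
    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    return np.squeeze(data)


def save_phantom(directory, phantom, seed: int = 0) -> None:
    """Write the phantom set as NIfTI slices plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    px = phantom.grid.pixel_size
    save_image(directory / "activity.nii.gz", phantom.activity, px)
    save_image(directory / "mu511.nii.gz", phantom.mu511, px)
    save_image(directory / "xct80.nii.gz", phantom.xct80, px)
    for i, name in enumerate(("air", "soft", "bone")):
        save_image(directory / f"fraction_{name}.nii.gz",
                   phantom.fractions[..., i], px)
    rois = phantom.roi_liver.astype(np.int16) + 2 * phantom.roi_bone.astype(np.int16)
    save_image(directory / "rois.nii.gz", rois, px)
    sidecar = {
        "pixel_size_cm": px,
        "seed": seed,
        "shape": list(phantom.grid.shape),
        "roi_labels": {"liver": 1, "bone": 2},
        "material_table": {
            "mu80": phantom.table.mu80, "mu511": phantom.table.mu511,
        },
    }
    (directory / "phantom.json").write_text(json.dumps(sidecar, indent=2))


def save_sinogram(path, y: np.ndarray, r: np.ndarray, scale: float,
                  geometry, seed: int) -> None:
    """Store a simulated scan (counts + background + metadata) in HDF5."""
    with h5py.File(str(path), "w") as f:
        f.create_dataset("y", data=y)
        f.create_dataset("r", data=r)
        f.attrs["scale"] = scale
        f.attrs["seed"] = seed
        for key in ("n_angles", "n_radial", "radial_spacing", "n_tof",
                    "tof_fwhm", "tof_bin_width"):
            f.attrs[key] = getattr(geometry, key)


def load_sinogram(path):
    """Load (y, r, attrs) from an HDF5 scan file."""
    with h5py.File(str(path), "r") as f:
        return f["y"][()], f["r"][()], dict(f.attrs)


def save_kernel(path, kernel: SparseKernelMatrix) -> None:
    """Persist a sparse kernel matrix (CSR arrays + metadata) in HDF5."""
    K = kernel.K.tocsr()
    with h5py.File(str(path), "w") as f:
        f.create_dataset("data", data=K.data)
        f.create_dataset("indices", data=K.indices)
        f.create_dataset("indptr", data=K.indptr)
        f.attrs["shape"] = K.shape
        f.attrs["k"] = kernel.k
        f.attrs["sigma"] = kernel.sigma
        f.attrs["kind"] = kernel.kind
        f.attrs["row_normalized"] = kernel.row_normalized


def load_kernel(path) -> SparseKernelMatrix:
    with h5py.File(str(path), "r") as f:
        K = csr_matrix((f["data"][()], f["indices"][()], f["indptr"][()]),
                       shape=tuple(f.attrs["shape"]))
        return SparseKernelMatrix(K=K, k=int(f.attrs["k"]),
                                  sigma=float(f.attrs["sigma"]),
                                  kind=str(f.attrs["kind"]),
                                  row_normalized=bool(f.attrs["row_normalized"]))


def grid_from_sidecar(path) -> ImageGrid:
    meta = json.loads(Path(path).read_text())
    return ImageGrid(meta["shape"][0], meta["shape"][1], meta["pixel_size_cm"])
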