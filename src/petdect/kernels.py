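"""Pixel feature maps and the kNN-sparsified Gaussian kernel matrix.

The attenuation image is represented as ``mu = K @ alpha`` where ``K`` encodes
similarity between pixels of an anatomical prior (the X-ray CT).  Features per
pixel are either raw intensity patches or channels of a CNN layer; similarity
is a radial Gaussian kernel on standardized features, sparsified to the k
nearest neighbours of each pixel and row-normalized so constant images are
represented exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix, identity
from scipy.spatial.distance import cdist


@dataclass
class FeatureMap:
    """Per-pixel feature vectors, one row per pixel in row-major image order."""

    features: np.ndarray  # (N_p, C)
    kind: str = "patch"  # {"patch", "cnn"}
    normalized: bool = False

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[1] < 1:
            raise ValueError("features must be a (N_p, C) array with C >= 1")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")

    @property
    def n_pixels(self) -> int:
        return self.features.shape[0]

    @property
    def n_channels(self) -> int:
        return self.features.shape[1]


@dataclass
class SparseKernelMatrix:
    """Row-stochastic kNN-sparsified Gaussian kernel over image pixels."""

    K: csr_matrix
    k: int
    sigma: float
    kind: str = "patch"
    row_normalized: bool = True

    @property
    def shape(self):
        return self.K.shape

    @classmethod
    def identity(cls, n_pixels: int) -> "SparseKernelMatrix":
        """K = I; reduces kernelized reconstruction to the standard one."""
        return cls(K=identity(n_pixels, format="csr"), k=1, sigma=1.0,
                   kind="identity")


def extract_patch_features(image: np.ndarray, patch_side: int = 3) -> FeatureMap:
    """Intensity patches centred at each pixel, replicate-padded at borders.

    Channel order is the raster order of the patch, so channel (C-1)/2 is the
    center-pixel intensity.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    if patch_side % 2 == 0 or patch_side < 1:
        raise ValueError("patch_side must be odd and positive")
    if patch_side > min(image.shape):
        raise ValueError("patch larger than image")
    half = patch_side // 2
    padded = np.pad(image, half, mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(padded, (patch_side, patch_side))
    feats = windows.reshape(image.size, patch_side * patch_side)
    return FeatureMap(features=np.ascontiguousarray(feats), kind="patch")


def normalize_features(fmap: FeatureMap) -> FeatureMap:
    """Standardize each channel to zero mean, unit SD; constant channels -> 0.

    Constancy is detected by zero peak-to-peak range, not by the computed SD:
    the mean of bit-identical values can round away from them, leaving a
    spurious SD of a few ulp.
    """
    f = fmap.features
    varying = f.max(axis=0) > f.min(axis=0)
    mean = f.mean(axis=0)
    sd = np.where(varying, f.std(axis=0), 1.0)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        out = np.where(varying, (f - mean) / sd, 0.0)
    # channels too degenerate to standardize (e.g. subnormal range) -> zero
    bad = ~np.all(np.isfinite(out), axis=0)
    if np.any(bad):
        out[:, bad] = 0.0
    return FeatureMap(features=out, kind=fmap.kind, normalized=True)


def _knn_indices(features: np.ndarray, k: int, chunk: int = 1024):
    """Deterministic kNN: self first, then ascending distance with ties broken
    by lower pixel index.

    Exhaustive chunked search with a stable sort, so degenerate feature maps
    (all-equal rows) still yield a reproducible neighbour set that keeps the
    diagonal entry in every row.
    """
    n = features.shape[0]
    idx = np.empty((n, k), dtype=np.int64)
    d2 = np.empty((n, k))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        dist = cdist(features[start:stop], features, metric="sqeuclidean")
        # pin the self pixel to rank first even under exhaustive ties
        dist[np.arange(stop - start), np.arange(start, stop)] = -1.0
        order = np.argsort(dist, axis=1, kind="stable")[:, :k]
        idx[start:stop] = order
        d2[start:stop] = np.maximum(np.take_along_axis(dist, order, axis=1), 0.0)
    return idx, d2


def build_kernel_matrix(fmap: FeatureMap, k: int = 50, sigma: float = 1.0,
                        row_normalize: bool = True) -> SparseKernelMatrix:
    """Assemble the sparse radial-Gaussian kernel matrix K.

    For each pixel j the k nearest pixels in Euclidean feature distance (self
    included) receive weight exp(-||f_j - f_l||^2 / (2 sigma^2)); rows are then
    normalized to sum to one.
    """
    n = fmap.n_pixels
    if k > n:
        raise ValueError(f"k={k} exceeds number of pixels {n}")
    if k < 1 or sigma <= 0:
        raise ValueError("k must be >= 1 and sigma > 0")
    idx, d2 = _knn_indices(fmap.features, k)
    w = np.exp(-d2 / (2.0 * sigma * sigma))
    if row_normalize:
        w /= w.sum(axis=1, keepdims=True)
    rows = np.repeat(np.arange(n), k)
    K = csr_matrix((w.ravel(), (rows, idx.ravel())), shape=(n, n))
    return SparseKernelMatrix(K=K, k=k, sigma=sigma, kind=fmap.kind,
                              row_normalized=row_normalize)
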