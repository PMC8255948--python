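import numpy as np
import pytest

from petdect import (ImageGrid, ScannerGeometry, build_system, make_phantom,
                     simulate_scan, test_scale_geometry)


@pytest.fixture(scope="session")
def grid64():
    return ImageGrid(64, 64, 63.0 / 64.0)


@pytest.fixture(scope="session")
def phantom64(grid64):
    return make_phantom(grid64, seed=0)


@pytest.fixture(scope="session")
def sys64(grid64):
    return build_system(grid64, test_scale_geometry(grid64))


@pytest.fixture(scope="session")
def scan64(phantom64, sys64):
    y, r, scale, _ = simulate_scan(phantom64, total_events=2e5,
                                   background_fraction=0.4, seed=1, sys=sys64)
    return y, r, scale


@pytest.fixture(scope="session")
def small_system():
    """12x12 grid with a coarse ring, for fast likelihood-level tests."""
    grid = ImageGrid(12, 12, 1.0)
    geom = ScannerGeometry(n_angles=12, n_radial=16, radial_spacing=1.0,
                           n_tof=3, tof_fwhm=6.0, tof_bin_width=4.0)
    return build_system(grid, geom)


@pytest.fixture()
def random_instance(small_system):
    """Random nonnegative (lam, mu) with a noisy scan on the 12x12 system."""
    rng = np.random.default_rng(7)
    n_pix = small_system.grid.n_pixels
    lam = rng.random(n_pix) * 5.0
    mu = rng.random(n_pix) * 0.05
    from petdect import expected_counts
    r = np.full((small_system.shape[0], small_system.geometry.n_tof), 0.3)
    ybar = expected_counts(lam, mu, r, small_system)
    y = np.random.default_rng(8).poisson(ybar).astype(float)
    return lam, mu, r, y
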