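"""Orchestration of the full method-comparison experiment.

One configuration drives: phantom generation, autoencoder training on the CT
prior, kernel construction, simulation of N_r independent noisy scans, the
four reconstructions (standard MLAA, patch-kernel MLAA, RED-CNN-kernel MLAA,
U-Net-kernel MLAA), GCT metrics over the iteration sweep, and dual-energy
material decomposition at the reporting iteration.  All randomness derives
from the master seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .autoencoder import ConvAutoencoder
from .decomposition import decompose_image
from .evaluation import mse_db, roi_bias_sd
from .forward_model import simulate_scan
from .grid import ImageGrid
from .kernels import build_kernel_matrix, extract_patch_features, normalize_features
from .materials import convert_ct_to_511
from .mlaa import MLAA, KernelMLAA
from .phantom import make_phantom
from .projector import build_system, default_geometry
from . import io

METHODS = ("mlaa", "kernel", "red-kernel", "unet-kernel")
MATERIALS = ("air", "soft", "bone")


@dataclass
class ExperimentConfig:
    """Settings of one comparison experiment; YAML round-trips identically."""

    n_rows: int = 180
    n_cols: int = 180
    pixel_size: float = 0.35
    n_angles: int = 180
    n_radial: int = 200
    n_tof: int = 11
    timing_resolution_ps: float = 550.0
    total_events: float = 5e6
    background_fraction: float = 0.4
    methods: tuple = METHODS
    n_outer: int = 3000
    record_every: int = 100
    report_iteration: int = 600
    kernel_k: int = 50
    kernel_sigma: float = 1.0
    patch_side: int = 3
    ae_epochs: int = 300
    redcnn_width: int = 60
    unet_channels: tuple = (32, 64, 96, 112)
    unet_penultimate: int = 12
    n_realizations: int = 10
    master_seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        self.methods = tuple(self.methods)
        self.unet_channels = tuple(self.unet_channels)
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")
        if self.report_iteration > self.n_outer:
            raise ValueError("report_iteration exceeds n_outer")

    @property
    def grid(self) -> ImageGrid:
        return ImageGrid(self.n_rows, self.n_cols, self.pixel_size)

    @property
    def schedule(self) -> tuple:
        sched = set(range(0, self.n_outer + 1, self.record_every))
        sched.add(self.report_iteration)
        sched.add(self.n_outer)
        return tuple(sorted(sched))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["methods"] = list(self.methods)
        d["unet_channels"] = list(self.unet_channels)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def desk_config(**overrides) -> ExperimentConfig:
    """Reduced desk-scale profile: 64x64 grid, 5 TOF bins, 2e5 counts."""
    base = dict(
        n_rows=64, n_cols=64, pixel_size=63.0 / 64.0, n_angles=60, n_radial=96,
        n_tof=5, total_events=2e5, n_outer=200, record_every=25,
        report_iteration=200, ae_epochs=300, redcnn_width=32,
        unet_channels=(16, 32, 48, 56), n_realizations=3,
    )
    base.update(overrides)
    return ExperimentConfig(**base)


def build_kernels(cfg: ExperimentConfig, xct80: np.ndarray) -> dict:
    """Patch and autoencoder kernel matrices for the requested methods."""
    kernels = {}
    if "kernel" in cfg.methods:
        fmap = normalize_features(extract_patch_features(xct80, cfg.patch_side))
        kernels["kernel"] = build_kernel_matrix(fmap, k=cfg.kernel_k,
                                                sigma=cfg.kernel_sigma)
    for method, arch in (("red-kernel", "redcnn"), ("unet-kernel", "unet")):
        if method not in cfg.methods:
            continue
        ae = ConvAutoencoder(
            architecture=arch, epochs=cfg.ae_epochs, seed=cfg.master_seed,
            redcnn_width=cfg.redcnn_width, unet_channels=cfg.unet_channels,
            unet_penultimate=cfg.unet_penultimate,
        ).fit(xct80)
        fmap = normalize_features(ae.transform(xct80))
        kernels[method] = build_kernel_matrix(fmap, k=cfg.kernel_k,
                                              sigma=cfg.kernel_sigma)
    return kernels


def _make_estimator(method: str, sys, kernels, n_outer: int):
    if method == "mlaa":
        return MLAA(sys=sys, n_outer=n_outer)
    return KernelMLAA(sys=sys, kernel=kernels[method], n_outer=n_outer)


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run the full comparison; returns a results bundle.

    Bundle keys: ``phantom``, ``mse`` (DataFrame: method, realization,
    iteration, mse_db), ``roi`` (DataFrame: method, iteration, region, bias,
    sd), ``fraction_mse`` (DataFrame over materials at the reporting
    iteration), ``recons`` and ``fractions`` (per-method lists over
    realizations at the reporting iteration), ``partial`` flag.
    """
    grid = cfg.grid
    phantom = make_phantom(grid, seed=cfg.master_seed)
    geom = default_geometry(grid, n_angles=cfg.n_angles, n_radial=cfg.n_radial,
                            n_tof=cfg.n_tof,
                            timing_resolution_ps=cfg.timing_resolution_ps)
    sys = build_system(grid, geom)
    init_mu = convert_ct_to_511(phantom.xct80, phantom.table)
    kernels = build_kernels(cfg, phantom.xct80)

    mse_rows, partial = [], False
    snapshots: dict = {m: {} for m in cfg.methods}  # method -> iter -> [mu...]
    recons: dict = {m: [] for m in cfg.methods}
    fractions: dict = {m: [] for m in cfg.methods}
    truth = phantom.mu511.ravel()

    for real in range(1, cfg.n_realizations + 1):
        y, r_bg, _, _ = simulate_scan(
            phantom, total_events=cfg.total_events,
            background_fraction=cfg.background_fraction,
            seed=cfg.master_seed + real, sys=sys,
        )
        for method in cfg.methods:
            try:
                est = _make_estimator(method, sys, kernels, cfg.n_outer)
                est.fit(y, r=r_bg, init_mu=init_mu,
                        snapshot_iters=cfg.schedule)
            except Exception as exc:  # noqa: BLE001 - mark bundle partial
                partial = True
                mse_rows.append({"method": method, "realization": real,
                                 "iteration": -1, "mse_db": np.nan,
                                 "error": str(exc)})
                continue
            for it, mu in est.snapshots_.items():
                snapshots[method].setdefault(it, []).append(mu)
                mse_rows.append({"method": method, "realization": real,
                                 "iteration": it,
                                 "mse_db": mse_db(mu, truth)})
            mu_report = est.snapshots_[cfg.report_iteration]
            recons[method].append(mu_report.reshape(grid.shape))
            fractions[method].append(decompose_image(
                phantom.xct80, mu_report.reshape(grid.shape),
                U=phantom.table.basis_matrix()))

    roi_rows = []
    for method in cfg.methods:
        for it, mus in sorted(snapshots[method].items()):
            if len(mus) < 2:
                continue
            for region, mask in (("liver", phantom.roi_liver),
                                 ("bone", phantom.roi_bone)):
                bias, sd = roi_bias_sd(
                    [m.reshape(grid.shape) for m in mus], phantom.mu511, mask)
                roi_rows.append({"method": method, "iteration": it,
                                 "region": region, "bias": bias, "sd": sd})

    frac_rows = []
    for method in cfg.methods:
        for real, frac in enumerate(fractions[method], start=1):
            for i, mat in enumerate(MATERIALS):
                frac_rows.append({
                    "method": method, "realization": real, "material": mat,
                    "iteration": cfg.report_iteration,
                    "mse_db": mse_db(frac[..., i], phantom.fractions[..., i]),
                })

    bundle = {
        "config": cfg,
        "phantom": phantom,
        "mse": pd.DataFrame(mse_rows),
        "roi": pd.DataFrame(roi_rows),
        "fraction_mse": pd.DataFrame(frac_rows),
        "recons": recons,
        "fractions": fractions,
        "partial": partial,
    }
    if cfg.output_dir:
        _write_bundle(bundle, Path(cfg.output_dir))
    return bundle


def _write_bundle(bundle: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg: ExperimentConfig = bundle["config"]
    cfg.to_yaml(out / "config.yaml")
    io.save_phantom(out / "phantom", bundle["phantom"])
    bundle["mse"].to_csv(out / "mse.csv", index=False)
    bundle["roi"].to_csv(out / "roi_bias_sd.csv", index=False)
    bundle["fraction_mse"].to_csv(out / "fraction_mse.csv", index=False)
    px = cfg.pixel_size
    for method in cfg.methods:
        for real, mu in enumerate(bundle["recons"][method], start=1):
            io.save_image(out / f"gct_{method}_r{real}.nii.gz", mu, px)
        for real, frac in enumerate(bundle["fractions"][method], start=1):
            for i, mat in enumerate(MATERIALS):
                io.save_image(out / f"frac_{mat}_{method}_r{real}.nii.gz",
                              frac[..., i], px)


def mean_mse_at(bundle: dict, iteration: int) -> dict:
    """Mean GCT MSE (dB) per method at one scheduled iteration."""
    df = bundle["mse"]
    sel = df[df["iteration"] == iteration]
    return sel.groupby("method")["mse_db"].mean().to_dict()
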