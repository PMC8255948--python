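# petdect — PET-enabled dual-energy CT

`petdect` simulates and reconstructs **γ-ray CT (GCT)**: a 511 keV attenuation
image estimated from time-of-flight PET emission data alone, which — paired
with the scanner's ordinary low-energy X-ray CT — turns any TOF-PET/CT into a
dual-energy CT system with no extra hardware, dose or scan time.  It is aimed
at researchers in quantitative PET/CT and tomographic reconstruction who want
a compact, fully inspectable 2D testbed for joint activity/attenuation
estimation and anatomically-guided (kernelized) reconstruction.

## The method

TOF-PET counts are Poisson with expectation

```
ȳ_m(λ, μ) = diag{n_m(μ)} G_m λ + r_m ,     n_m(μ) = c · exp(−A μ) ,
```

where `λ` is the activity image, `μ` the 511 keV attenuation image, `G_m` the
TOF detection operator of time bin `m`, `A` the transmission (line-integral)
operator and `r` the random/scatter background.  **MLAA** maximizes the
Poisson log-likelihood `L(y | λ, μ)` jointly, alternating a multiplicative
MLEM update of `λ` with a safeguarded separable-paraboloidal-surrogate (SPS)
ascent step on `μ`.

**Kernel MLAA** constrains `μ = Kα`, where the sparse row-stochastic kernel
matrix `K` encodes pixel similarity in the X-ray CT prior:
`K_jl ∝ exp(−‖f_j − f_l‖²/2σ²)` over the k = 50 nearest neighbours.  The
feature vector `f_j` is either a 3×3 intensity patch, or the penultimate-layer
activation of a convolutional autoencoder (RED-CNN or U-Net) trained,
unsupervised, to reproduce the prior image itself.  The SPS step is pulled
back through `K` onto the coefficient image `α`.

Finally each pixel's dual-energy pair `u_j = (x_j, μ_j)` is decomposed by
constrained least squares `min ‖u_j − U ρ_j‖², Σρ = 1` into air / soft-tissue
/ bone fractions with a NIST-derived 2×3 basis matrix `U`.

Everything ships as scikit-learn style estimators (`MLAA`, `KernelMLAA`,
`ConvAutoencoder`, `MaterialDecomposer`) plus functional wrappers, a YAML
driven experiment runner and a `petdect` command-line interface.

## Worked example

```python
import petdect as pd

grid = pd.ImageGrid(64, 64, 63 / 64)            # 64×64, ~1 cm pixels
phantom = pd.make_phantom(grid, seed=0)          # synthetic chest slice
sys = pd.build_system(grid, pd.test_scale_geometry(grid))
y, r, scale, _ = pd.simulate_scan(phantom, total_events=2e5,
                                  background_fraction=0.4, seed=1, sys=sys)

init = pd.convert_ct_to_511(phantom.xct80, phantom.table)
std = pd.MLAA(sys=sys, n_outer=200).fit(y, r=r, init_mu=init)

feats = pd.normalize_features(pd.extract_patch_features(phantom.xct80))
K = pd.build_kernel_matrix(feats, k=50)
ker = pd.KernelMLAA(sys=sys, kernel=K, n_outer=200).fit(y, r=r, init_mu=init)

for name, est in [("standard MLAA", std), ("patch-kernel MLAA", ker)]:
    print(f"{name}: GCT MSE {pd.mse_db(est.mu_, phantom.mu511.ravel()):.2f} dB")
```

prints (seeds as above):

```
standard MLAA: GCT MSE -10.03 dB
patch-kernel MLAA: GCT MSE -21.57 dB
```

i.e. after 200 iterations the anatomically-guided reconstruction has an order
of magnitude lower squared error than unguided MLAA — the prior suppresses
the noise that joint activity/attenuation estimation otherwise accumulates.
Decomposing `(phantom.xct80, est.mu_)` with `pd.decompose_image` then yields
the air/soft/bone fraction maps.

The full four-method comparison (adds the RED-CNN and U-Net autoencoder
kernels) runs from one config:

```bash
petdect run --config configs/desk.yaml
```

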