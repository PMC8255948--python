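# Methods

## Forward model and simulation

The scanner is a generic 2D parallel-beam ring: `n_angles` views over 180°,
`n_radial` offsets per view (spacing = pixel size).  The transmission
operator `A` holds exact pixel intersection lengths (cm) from Siddon ray
tracing, so `exp(−Aμ)` is the photon survival probability along each line of
response.  Time-of-flight is modeled in image space: each TOF bin's operator
`G_m` reweights the geometric path by a Gaussian profile centered on the bin,
with spatial FWHM `c·Δt/2 ≈ 8.24 cm` for a 550 ps coincidence resolution.
Bin weights integrate the Gaussian over each bin with open-ended outer bins
and are renormalized per ray–pixel pair, so `Σ_m G_m = A`'s weighting exactly
— TOF redistributes counts along the line, it never creates or destroys them.
Detector normalization factors `c` default to 1 (no detector effects are
simulated).

A scan scales the phantom activity so expected prompts equal `total_events`,
adds a uniform background with `Σr = background_fraction · Σȳ`
(default 0.4, i.e. background is 40 % of prompts; an alternative
trues-relative reading would use `Σr = 0.4 · Σtrues` and is obtained by
passing `background_fraction = 0.4/1.4`), and draws independent Poisson
counts from one seeded generator.

## Phantom

The chest slice is procedural: body outline, two lungs, liver, spine and two
hot lung lesions composed from ellipses in grid-relative coordinates, so the
anatomy scales with the grid (default 180×180 at 0.35 cm; the desk profile
uses 64×64 at ~1 cm).  Each pixel carries an (air, soft tissue, bone)
fraction triple; organs are rasterized on a 4× supersampled subgrid and
block-averaged, so boundary pixels hold partial-volume mixtures as a
voxelized anatomical phantom would.  Lung tissue is a 30 % soft / 70 % air
mixture (inflated-lung density); activity levels are lungs 0.5, soft 1.0,
liver 1.5, spine 0.5, lesions 4.0 (relative units).  The 80 keV CT and the
511 keV attenuation truth are computed *exactly* from the fractions with
NIST XCOM coefficients (water 0.1837 / 0.0959 cm⁻¹, ICRU-44 cortical bone at
1.92 g/cc: 0.4280 / 0.1732 cm⁻¹), which gives the package a machine-precision
round-trip property: decomposing the noise-free `(xct80, mu511)` pair
recovers the generating fractions.  The X-ray CT is converted to an initial
511 keV map by the standard bilinear (water/bone two-segment) scaling.

## MLAA and the kernelized attenuation step

MLEM updates the activity with attenuation fixed; the attenuation step is a
gradient ascent with the separable-surrogate curvature
`d_j = [Aᵀ(γ ⊙ Σ_m t_m)]_j` (`γ_i` = ray length through the image,
`t = n ⊙ Gλ`), projected to `μ ≥ 0`.  Because this precomputed curvature
does not guarantee monotonicity when a background term is present, every
attenuation step carries a step-halving safeguard (up to 10 halvings, then
revert), making the recorded log-likelihood trace non-decreasing by
construction — an audited invariant, not an assumption.

In kernel mode the same step acts on `α` through `g_α = Kᵀ g_μ`,
`d_α = Kᵀ d_μ` (using `K·1 = 1`), and `μ = Kα`.  With `K = I` the kernel
path is bit-identical to the standard one.  `α` is initialized by solving
`min ‖Kα − μ⁰‖, α ≥ 0` with multiplicative (ISRA) iterations rather than by
`α⁰ = μ⁰`: for kernels that smooth appreciably, `Kμ⁰` would discard much of
the accurate CT-derived initialization.  `λ` starts uniform, scaled to the measured trues; the
scale non-uniqueness of TOF-MLAA is left to the CT initialization to resolve,
with no further remedy.

Defaults: 1 MLEM + 1 SPS inner iteration per outer iteration, no ordered
subsets, 3000 outer iterations maximum with results reported at 600; the
desk profile runs 200 outer iterations on the 64×64 grid with 2×10⁵ counts,
5 TOF bins and N_r = 3 noise realizations, which keeps the complete
four-method comparison within minutes on one CPU.

## Kernel construction

Features per pixel: 3×3 replicate-padded intensity patches, or the
penultimate-layer activation of the trained autoencoder (U-Net: 12 channels).
Channels are standardized to zero mean / unit SD (constant channels map to
zero), the Gaussian width is σ = 1 on standardized features, and each row
keeps the k = 50 nearest pixels by Euclidean feature distance — a global
search (no spatial window), self always included, deterministic tie-break by
lower pixel index — then rows are normalized to sum to one, so constant
images are reproduced exactly.  The kNN search is an exhaustive chunked
distance computation with a stable sort: on degenerate feature maps (every
patch identical) library kNN implementations return an arbitrary tie order,
which would make reconstructions irreproducible.

## Autoencoders

The CNN engine is a small self-contained numpy stack (stride-1/2 same-padded
convolution, bilinear resize with exact adjoint, ReLU, Adam) with
hand-written backward passes, verified against numerical gradients to 1e-8.
RED-CNN: five 5×5 encoder convolutions and five decoder layers at full
resolution with additive skips (e4→d1, e2→d3, input→output); 60 filters per
hidden layer gives 723,541 parameters.  U-Net: 3×3 convolutions, stride-2
downsampling, bilinear upsampling, additive encoder→decoder skips, a
12-channel penultimate layer; widths (32, 64, 96, 112) give 345,353
parameters.  Training minimizes `‖x − ϕ(θ; x)‖²` on the single [0,1]-scaled
prior image for 300 epochs of full-image Adam steps (learning rates 1e-4 for
RED-CNN, 1e-2 for U-Net); it is bit-reproducible for a fixed seed and runs in
seconds to minutes on one CPU in float32.  The desk profile narrows the
models (RED-CNN width 32, U-Net (16, 32, 48, 56)) — parameter counts do not
depend on image size, but the narrower models train stably at the desk
image size where the full-width U-Net's initialization scale stalls
optimization within the 300-epoch budget.  The RED-CNN feature layer is the
last hidden decoder activation; any full-resolution layer can be selected,
and selecting a downsampled layer is an error.

## Decomposition and metrics

Material decomposition eliminates `ρ_air = 1 − ρ_soft − ρ_bone` and solves
the remaining 2×2 system in closed form per pixel; only the sum constraint is
enforced, so noisy inputs may push individual fractions outside [0, 1]
(optional clipping is off by default).  The reduced design has one small
singular value (~0.018 cm⁻¹): dual-energy decomposition is intrinsically
ill-conditioned along one direction of the constraint plane, which is why
fraction-image errors are much larger (in dB) than GCT errors.

Metrics follow the standard ensemble protocol: image MSE as
`10·log10(‖est−truth‖²/‖truth‖²)` over all pixels; ROI bias and SD of the
ROI-mean across N_r realizations normalized by the true ROI mean (unbiased
N_r−1 variance); the pixel-based variant applies the same formulas per pixel
and averages over a region, in percent.

## What the desk-scale simulation shows — and does not

The synthetic study reproduces the structural properties of the method: the
likelihood machinery (monotone updates, fixed points, K = I equivalence,
adjoint-exact operators), the strong noise suppression of anatomically-guided
kernel MLAA over standard MLAA, and the end-to-end dual-energy pipeline.

It does **not** reproduce the relative ranking of feature types reported for
realistic anatomy.  Because the phantom's CT prior is noise-free and computed
exactly from a handful of material classes, 3×3 intensity patches are a
near-perfect tissue-class indicator — all interior same-class patches are
bit-identical and classes are widely separated — so the patch kernel's
smoothing error sits near the achievable floor and patch-kernel MLAA is the
strongest method on this phantom, at the desk scale and at the full grid
alike.  The autoencoder features remain substantially coarser, so the CNN
kernels land between standard MLAA and the patch kernel.  On real or
textured priors — where raw patches are noisy and ambiguous — the learned
features' robustness is the point; a piecewise-exact synthetic prior removes
precisely that challenge.  Passing tests on this phantom therefore validate
correctness and the guided-vs-unguided ordering, not feature-learning
superiority on clinical data.

## Numerical choices

Ray tracing drops segments below 1e-12 × pixel size; TOF operator entries
below 1e-14 are pruned (bounded by ~1e-13 relative on `Σ_m G_m = A`).
Likelihood terms use the convention `0·log 0 = 0`; bins with `ȳ = 0, y > 0`
raise.  SPS pixels with zero curvature and nonzero gradient are frozen with
a warning.  MLEM freezes pixels with zero sensitivity.  The ISRA α
initialization runs 200 iterations.  All seeds flow from one master seed;
simulation realization r uses `master_seed + r`.
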