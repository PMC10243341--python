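# Methods

This note records the models, conventions, and numerical choices behind
`perfct`, and what the synthetic experiments do and do not establish.

## Forward model and units

Images are single-slice dynamic series `(ny, nx, nt)`; frame `i` is sampled
at `t = i·dt` seconds. CT numbers (HU) and attenuation (cm⁻¹) are related
affinely through the water/air calibration `μ = 0.239·(HU/1000 + 1)`,
clipped below at zero; 0.239 cm⁻¹ is the attenuation of water at the
effective energy of an 80 kVp beam. The forward model is monoenergetic:
line integrals are `Σ μ_j ℓ_j` with Siddon intersection lengths in cm, so
sinogram entries are dimensionless.

The scanner is an equiangular fan beam: by default 1000 views over 360°,
377 detectors on a source-centered arc, source-isocenter 570 mm,
isocenter-detector 470 mm. The fan half-angle is derived to cover the
image-inscribed circle with a one-bin margin (the detector pitch follows
from it). Pixels are centered on the isocenter, x right, y up.

Counting noise follows Beer-Lambert: expected surviving photons
`I = I₀·e^{−P}` with `I₀ = 2.5×10⁵` per ray by default, a Poisson draw,
additive Gaussian readout noise of variance 10 counts², and a clamp of
non-positive counts to one before the log. Each frame has an independent
substream derived from `(seed, frame)`.

### Reconstruction support

Pixels outside the inscribed FOV circle are crossed by few or no rays and
are effectively in the null space of the system operator; left free they
drift by hundreds of HU and dominate any whole-image error metric. Both
FBP and the iterative solver therefore constrain reconstructions to the
FOV circle (outside: μ = 0).

## Phantom

The brain slice is built from simple shapes so every pixel has exact ground
truth: a brain disc (radius 0.40 of the grid) inside a skull annulus
(0.42–0.47), gray matter in the upper half-plane, white matter in the
lower, two ventricular CSF discs, a vessel disc standing in for the
internal carotid artery (with a 20×20-equivalent AIF extraction square),
and optionally concentric penumbra/core discs in the gray matter with a
mirrored 18×18-equivalent contralateral-normal square. ROI edge lengths are
stated on the 256-pixel grid and scaled proportionally on smaller grids.

Default tissue parameters (standard adult physiology; only relative
behavior is asserted against them):

| tissue | baseline HU | CBF mL/100g/min | CBV mL/100g | MTT s |
|--------|------------:|----------------:|------------:|------:|
| gray matter  | 40 | 60 | 4.0 | 4.0 |
| white matter | 30 | 25 | 2.0 | 4.8 |
| penumbra     | 40 | 24 (×0.4) | 3.6 (×0.9) | 9.0 |
| ischemic core| 40 |  9 (×0.15)| 1.6 (×0.4) | 10.7 |
| CSF 15 HU, skull 1000 HU, vessel 45 HU | | non-perfused / AIF carrier | | |

The arterial input is a gamma-variate with 150 HU peak, 10 s delay (so the
first eight 1 s frames are pure baseline), shape 3, scale 1.5 s. Vessel
pixels carry the AIF directly.

### Discrete-exponential residue

Tissue curves follow the indicator-dilution convolution
`CE(t) = (ρ/k_H)·CBF·(AIF ⊛ R)(t)` evaluated as a rectangle-rule discrete
convolution on the frame grid. The residue is the *discrete* exponential
`R_j = (1 − dt/MTT)^j`: a mono-exponential whose decay rate is renormalized
so its rectangle-rule area is exactly MTT. A plain sampled `exp(−t/MTT)`
cannot satisfy both `R(0) = 1` (which fixes CBF via the deconvolved curve
maximum) and area = MTT (which fixes CBV via the area ratio) at 1 s
sampling — its rectangle area is `dt/(1−e^{−dt/MTT}) ≈ MTT + dt/2`, a 13%
CBV bias at MTT = 4 s. With the discrete-exponential residue the
convolution/deconvolution pair is exactly consistent at any `dt`
(requires MTT > dt), and noise-free parameter recovery is limited only by
the truncation tail of the 50 s acquisition (<0.1% for GM/WM; long-MTT
lesion tissue keeps a percent-level truncation artifact).

## Perfusion quantification

Contrast enhancement subtracts the per-pixel mean of frames 1–8. The AIF is
the membership-weighted mean curve of the fuzzy-c-means cluster (5 clusters,
fuzziness 2.0, tolerance 10⁻⁵, ≤300 iterations, seeded initialization) with
the largest peak enhancement inside the arterial ROI. Deconvolution builds
the block-circulant matrix of the AIF zero-padded to length 2N (rectangle
discretization, delay-insensitive), truncates singular values below a
fraction of σ_max, and reads CBF from the maximum of the scaled residue,
with the unit conversion `(k_H/ρ)·max(k)·6000` to mL/100 g/min. CBV is
`(k_H/ρ)·(ΣCE_tissue/ΣCE_AIF)·100` with full-series rectangle sums as the
integral surrogate; MTT = 60·CBV/CBF holds exactly by construction wherever
CBF exceeds 10⁻³ (other pixels are flagged non-perfused and zeroed).

The truncation threshold defaults to 10% of σ_max — the convention for
noisy clinical data. On *noise-free* data this truncation is pure bias
(≈30% CBF underestimation); recovery analyses therefore pass an explicit
near-zero threshold, which is exact for the discrete-consistent forward
model. Constants: ρ = 1.04 g/mL, k_H = 0.73; a pure blood pixel yields the
CBV ceiling 100·k_H/ρ ≈ 70.2 mL/100 g.

## Primal-dual solver

All four objectives are solved by the Chambolle-Pock iteration with
extrapolation θ = 1: the quadratic data term is dualized with resolvent
`q ← (q + σ(Āx̄ − b̄))/(1 + σ)`; each isotropic ℓ₁ term is dualized with a
pointwise projection onto the ball of its weight (symmetric-tensor
magnitudes carry weight 2 on off-diagonals); the nuclear norm enters as a
primal prox by singular-value soft-thresholding of the Casorati matrix.
Forward differences with replicate boundaries define ∇₃ and E; their
adjoints are exact (verified to 10⁻⁹). Initialization is the Ram-Lak FBP
series (for L+S methods: L, with S = 0); stopping at relative change
`‖xⁿ⁺¹−xⁿ‖_F/‖xⁿ‖_F < 10⁻⁶` or 500 iterations (desk-scale presets use
150). The solver is fully deterministic.

### Normalization conventions

The published step sizes σ = τ = 0.25 are only meaningful for a normalized
operator, and the weights α, β are only meaningful relative to a data-term
scale; with the underlying algorithm details unavailable, the package fixes
its own convention and documents it:

- The iteration (equivalently, the objective up to a positive factor) uses
  the system operator rescaled to unit spectral norm (power iteration, 50
  steps, deterministic start), with the data as `b/‖A‖`. On this scale
  σ = τ = 0.25 satisfies the convergence condition for TV
  (σ·τ·‖K‖² ≈ 0.8 < 1); for the TGV variants the composite operator norm is
  estimated by power iteration per method, and if σ·τ·‖K‖² > 0.99 both
  steps are scaled down jointly (reported in `SolveReport`).
- α (and α₁, with α₀ = 2α₁) weigh the gradient terms against this
  unit-norm data term. On this scale the range 10⁻⁴…10⁻² spans the
  under- to over-regularized regimes of the desk-scale experiment, with
  β = 2.0 as the nuclear weight applied to the *per-frame* nuclear norm
  `‖L‖★/N_f`. The per-frame normalization puts the singular-value
  threshold at the scale separating the static anatomy mode (σ₁ ≈ 40 in
  attenuation units) from noise and contrast dynamics (σ ≲ 1), and keeps
  that separation independent of series length. Both alternatives —
  thresholding the raw nuclear norm (crushes the background into the
  TGV-smoothed S) and dividing β by ‖A‖² (leaves L an unregularized
  least-squares fit) — demonstrably destroy the intended
  background/dynamics split.
- The solver works in attenuation units; outputs are converted to HU
  (for L+S, L converts affinely and S linearly, so L + S reproduces the
  reconstruction in HU exactly).

### Degenerate inputs

A zero-norm previous iterate falls back to the absolute change in the
stopping rule; single-frame series zero the temporal gradient with a
warning; relative change above 10⁶ (or non-finite) aborts with a step-size
diagnostic.

## Evaluation

PSNR is `−10·log₁₀(MSE/max(ref)²)` over the whole 4D series in HU
(identical inputs report infinity). SSIM uses the standard defaults
(11×11 Gaussian window, σ = 1.5, K₁ = 0.01, K₂ = 0.03, sample-size-free
normalization) with the dynamic range taken per frame from the reference
max−min, averaged over frames. Regression of perfusion maps on the
reference is ordinary least squares restricted to the brain mask. ROI
statistics are arithmetic means and population SDs. The sweep driver
reconstructs each (method, α) pair from a shared FBP initializer and
emits a tidy table.

## Desk scale: what it shows and what it does not

The test suite and the acceptance script run a scaled-down study: the same
256 mm head sampled on a 64×64 grid of 4 mm pixels, 16–24 frames, 144
views × 96 detectors, 150 iterations. Keeping the physical head size is
essential — ray attenuation (line integrals up to ≈6.5, i.e. a few hundred
surviving photons at I₀ = 2.5×10⁵) and therefore the post-log noise match
the full-scale acquisition. The full-scale preset (256×256, 50 frames,
1000×377, 500 iterations) is hours of CPU and is exercised structurally,
not numerically, by the tests.

Reproduced at desk scale:

- the L+S variants' peak PSNR strictly above TV/TGV, and their SSIM
  plateau (≈0.95) across the whole weight grid while TV/TGV collapse at
  large weights;
- the stability ordering — ROI-mean perfusion values vary far less across
  the strong half of the weight grid for TGV (and trivially for LTGV) than
  for TV;
- the TGV-over-TV advantage on smooth-plus-edges content (3× lower RMSE on
  a noisy affine ramp), i.e. the absence of staircase artifacts.

Not reproduced, and why:

- **Absolute α peak locations.** They depend on the unknowable original
  operator scaling; only orderings and trends are asserted.
- **Regularized methods beating FBP(RL) in PSNR.** The reference is
  defined as the noise-free Ram-Lak FBP, so the noisy FBP shares its
  systematic blur and is penalized only for noise, while iterative
  solutions carry their own (different) bias. At 4 mm pixels every phantom
  structure is 1–3 pixels wide, which further favors the shared-bias
  baseline. The same effect makes FBP(SL) score below FBP(RL) here.
- **Clinically calibrated perfusion values from noisy reconstructions.**
  Reconstructing ≈3 HU contrast dynamics at low dose through strong
  regularizers attenuates CE amplitudes; desk-scale map values are
  meaningful relatively (between methods, across α), not absolutely.

The phantom itself omits partial-volume mixing at tissue borders,
beam-hardening/polyenergetic effects, scatter, motion, and 3D geometry;
tissues are piecewise-constant in space, which is TV's ideal prior and
therefore *understates* TGV's advantage relative to anatomically smooth
real data.
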