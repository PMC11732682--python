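# Methods

## The registration model

Given a moving image X_mv and a fixed image X_fx on a common voxel grid
Ω ⊂ R³, deformable registration seeks a transformation φ : R³ → R³ with

    X_wp = X_mv ∘ φ ≈ X_fx,

where warping samples the moving image at x + φ(x) for every fixed-grid
voxel x (φ is a dense displacement field in voxel units).  Instead of a
single network predicting φ, the model stacks n convolutional
encoder–decoder networks ("cascades").  Cascade k consumes the current
warped image and the fixed image and emits a *partial* field φ_k; the
running sum Σ_{i≤k} φ_i is applied to the **original** moving image to
produce the next warped image:

    X_wp,n = X_mv ∘ Σ_{i=1..n} φ_i.

Accumulating the partial fields and warping the original image once per
step avoids compounding interpolation error; the alternative
(no-accumulation) mode, kept for comparison, warps the previously warped
image by each new φ_k and composes the partials functionally
(φ∘ψ evaluated as φ(x + ψ(x)) + ψ(x), first-listed field acting first).
Earlier cascades capture coarse, low-frequency deformation; later ones
refine high-frequency detail.

### Backbone

Each cascade is a 3-D U-Net-style network in a *contracted* configuration:
relatively wide hidden feature maps, and **no convolution at full image
resolution** — the last decoder stage stops at half resolution, where a
zero-initialized 3×3×3 convolution emits the 3-channel field, which is then
trilinearly upsampled ×2 (vectors scaled by 2 to stay in voxel units).
Zero-initializing the emission layer makes an untrained cascade exactly the
identity map, which stabilizes early training and gives a testable
contract.  Cascades do not share parameters.  Activations are leaky
rectifications (slope 0.2).  Desk-profile channel plan: encoder (8, 16, 16)
with stride-2 convolutions, decoder (16, 8) with trilinear upsampling and
skip concatenations.

The package has no GPU dependency: the networks, the spatial-transformer
warp and the losses run on a small reverse-mode autodiff engine over numpy
(`morphcascade.autodiff`), with conv3d via im2col matrix products and exact
adjoint operators for the warp, window-sum and upsampling primitives.
Every primitive's gradient is verified against central finite differences
in the test suite.

### Objective

The loss on the *final* outputs only (no per-cascade supervision) is

    L = −CC(X_fx, X_wp,n) + λ · mean_p ‖∇φ(p)‖²,

where CC is the local windowed normalized cross-correlation with a squared
numerator: for a window of edge d around voxel p,

    CC_p = ( Σ (X_fx − mean)(X_wp − mean) )² /
           ( (Σ (X_fx − mean)² + ε)(Σ (X_wp − mean)² + ε) ),

averaged over all voxels whose full d³ window lies inside Ω, so each term
is in [0, 1] and the loss attains −1 at perfect (anti-)correlation.
ε = 1e-5 guards constant windows.  The multi-resolution variant averages
CC over several window edges (default evaluation set {5, 7, 9, 11}),
giving long-range gradients from large windows and fine discrimination
from small ones.  The smoothness term uses forward differences over all
nine partials, averaged per-derivative-grid, so a translation costs 0 and
a uniform per-axis scaling by a costs exactly 3a².  Both terms are means
(not sums) over Ω so λ keeps one meaning across image sizes.

### Training

Adam, batch size 1–2, learning rate lr(ep) = base_lr · exp(−3 ep / EP_max)
(the decaying form; full-scale recipes quote base_lr = 3e-4 and
EP_max = 500 with 100 iterations per epoch).  After each epoch the
image-similarity term alone is evaluated on validation pairs and the best
checkpoint kept — the regularization term never enters model selection.
A NaN loss aborts with a diagnostic rather than being clipped.

### Desk profile

All shipped experiments run on one CPU core in minutes: 32³ volumes,
1–3 cascades, 30 epochs × 10 iterations, batch 1, base_lr = 2e-3,
λ = 0.1, similarity window d = 5.  The higher base learning rate and
lighter regularization relative to the full-scale recipe reflect the much
shorter optimization and the small, noise-dominated flat regions of the
32³ phantoms; they were fixed by a configuration sweep on the recovery
task before the acceptance thresholds were evaluated, and the cohort model
for multi-atlas segmentation trains for 60 epochs (it fits 380
inter-subject pairs rather than one).

## Transformation quality

Folding (local non-invertibility) is quantified by the Jacobian of
x ↦ x + φ(x): det(I + ∇φ) computed by central differences at interior
voxels only (one-sided differences at borders would inflate folding
estimates), and reported as the percentage of interior voxels with a
negative determinant.  A zero field gives det ≡ 1; an affine field
φ = 0.1·x per axis gives det ≡ 1.331 exactly.

## Multi-atlas segmentation

Every annotated atlas is registered to the target (atlas = moving), its
labels propagated along the final field with nearest-neighbour sampling.
Warped atlases are ranked by whole-volume NCC against the target on the
target's nonzero foreground (MSE and SSIM are available alternatives);
the best n_select (default 10 of 20) are fused:

- **MV** — per-voxel modal label;
- **LWV** — atlas k's vote at voxel i is weighted by |m_k(i)|^g, where
  m_k(i) is the windowed (d = 9) signed local NCC between warped atlas k
  and the target, clamped at 0 from below, and g = 2.

Ties always break toward the lowest class id, deterministically.

## Synthetic phantoms

The generator produces nested ellipsoidal "brain" phantoms with the seven
tissue classes used in fetal MRI segmentation (CSF shell, cortical shell
with a sinusoidal boundary perturbation, white matter, paired ventricles,
cerebellum, thalamus, brain stem), per-class mean intensities, additive
Gaussian noise (σ = 0.03, clipped to [0, 1]) and min–max normalization.
A scalar age ∈ [0, 1] maps linearly to overall size (±20 %) and cortical
boundary irregularity, giving a monotone morphology axis that emulates
gestational age across a cohort (ages evenly spaced, per-member seeds
derived from the base seed).  Ground-truth deformations are
Gaussian-smoothed white-noise fields (zero mean per component) rescaled so
the *peak* voxel displacement equals max_disp; at the default scales
(max_disp 4, σ_smooth 4 on 32³) they are fold-free.

What the phantoms do **not** emulate: MRI acquisition physics, bias
fields, partial-volume effects, motion or super-resolution artifacts, and
real anatomical variability.  Passing tests therefore demonstrate the
correctness and qualitative behaviour of the machinery — not clinical
performance.

## Endpoint error

The registration recovers (approximately) the *inverse* of the truth
field t, so φ and t are not directly comparable.  The reported endpoint
error is the mean norm of the composition residual

    EPE = mean_x ‖ φ(x) + t(x + φ(x)) ‖,

which equals the mean pre-registration displacement at φ = 0 and vanishes
iff φ is the exact inverse of t.  This avoids numeric field inversion.

## Numerical conventions

- Resampling grids include both endpoints per axis ("aligned endpoints"),
  so identity resizes are exact; intensities trilinear, labels
  nearest-neighbour.
- Out-of-domain warp samples clamp to the border voxel (replicate);
  zero-fill is available but produces dark halos that corrupt local NCC.
- Field I/O: 4-D NIfTI, last axis = vector components in grid-axis order,
  voxel units.
- Foreground cropping thresholds at intensity > 0 (skull-stripped inputs),
  margin 2 voxels; labels use unsigned 8-bit.
- HD95 applies the 95th percentile per direction and then the maximum
  (a pooled variant is available); distances are Euclidean between voxel
  centers scaled by spacing, all mask voxels participating (no surface
  extraction); percentiles interpolate linearly between closest ranks.
- Standard errors use σ/√n with the population σ (divisor n); a
  divisor-(n−1) flag exists.
- Pair sampling during training draws ordered pairs uniformly; self-pairs
  are excluded.

## Known limitations

- Desk-scale training budgets recover most but not all of a synthetic
  deformation: the local-NCC optimum sits slightly away from the true
  inverse in the presence of independent per-volume noise, and the double
  nearest-neighbour label transport (truth warp, then recovered warp) at
  32³ bounds the attainable Dice below 1 even for a perfect field.
- On this cohort of simple phantoms a near-age-twin atlas can outscore
  the 10-atlas fusion; with real anatomy (no exact twins) fusion is
  reported to win.
- The λ-folding trend is vacuous at desk scale when no configuration
  folds at all (all percentages 0), which the defaults produce by design.
- Diffeomorphic integration (scaling-and-squaring) and field inversion
  are out of scope.
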