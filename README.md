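# morphcascade

Cascaded deformable registration and weakly-supervised multi-atlas
segmentation for 3-D brain volumes, CPU-only, with a fully synthetic
phantom generator so the whole pipeline is testable end to end without any
data download.

## Who this is for

Researchers in volumetric medical image analysis (e.g. fetal or neonatal
brain MRI) who want a small, dependency-light, inspectable implementation
of unsupervised cascaded registration:

- **n stacked encoder–decoder networks** each predict a *partial*
  displacement field φ_k; the fields are **accumulated** (voxel-wise sum)
  and the original moving image is warped once per step, so
  X_wp,n = X_mv ∘ Σ φ_i — no interpolation-of-interpolation;
- the unsupervised loss L = −CC(X_fx, X_wp) + λ·mean‖∇φ‖² uses a local
  windowed normalized cross-correlation (squared numerator, windows from
  5³ to 11³ in the multi-resolution variant) computed on the *final*
  output only;
- a **contracted** backbone (wider hidden features, no full-resolution
  convolution; the field is emitted at half resolution and trilinearly
  upsampled) keeps memory low so more cascades fit;
- transformation quality is audited via the percentage of negative
  Jacobian determinants of x ↦ x + φ(x);
- a multi-atlas segmentation (MAS) pipeline registers every annotated
  atlas to a target, ranks the warped atlases by NCC, keeps the best ten
  and fuses their propagated labels by **local weighted voting**
  (ω_k,i = |m|^g with m the local NCC around voxel i), falling back to
  majority voting;
- evaluation: per-class Dice, 95th-percentile Hausdorff distance, standard
  errors σ/√n.

Everything — including the convolutional networks and their gradients —
runs on numpy/scipy via a compact reverse-mode autodiff module; there is
no GPU or deep-learning-framework dependency.

## Worked example

Synthesize a 32³ seven-tissue phantom pair linked by a known smooth
deformation, train a 3-cascade model on it, and measure recovery:

```python
from morphcascade.experiments import recovery_experiment

r = recovery_experiment(seed=1)
print(f"Dice before/after: {r['pre_dice']:.3f} -> {r['post_dice']:.3f}")
print(f"mean residual displacement: {r['pre_epe']:.2f} -> "
      f"{r['post_epe']:.2f} voxels")
print(f"negative-Jacobian fraction: {r['neg_jacobian_pct']:.3f} %")
```

```
Dice before/after: 0.782 -> 0.912
mean residual displacement: 1.33 -> 1.11 voxels
negative-Jacobian fraction: 0.000 %
```

The mean foreground Dice of the propagated labels rises from 0.78 to 0.91,
the residual displacement against the known truth field drops below the
pre-registration misalignment, and the recovered transformation is
fold-free.

The same workflows are available from the shell:

```bash
morphcascade synth --out data --size 32 --seed 1 --cohort 20
morphcascade train --data-dir data --out model --cascades 3 --epochs 30
morphcascade register --moving data/moving.nii.gz --fixed data/fixed.nii.gz \
    --checkpoint model/checkpoint.npz --out reg --save-partials
morphcascade segment --target data/fixed.nii.gz --atlas-dir data/cohort \
    --checkpoint model/checkpoint.npz --out seg --n-select 10 --fusion lwv
morphcascade evaluate --predicted seg/segmentation.nii.gz \
    --reference data/fixed_labels.nii.gz --out report
```

Each command writes a `manifest.json` sufficient to reproduce it exactly.

## Layout

| module | contents |
| --- | --- |
| `volume_io` | NIfTI I/O, crop / resize-to-cube / normalize preprocessing |
| `phantom` | multi-tissue phantoms, cohorts, smooth ground-truth fields |
| `transform` | warping, field accumulation/composition, Jacobian analysis |
| `losses` | local & multi-resolution NCC, smoothness, total objective |
| `network` | contracted backbone, cascade model, checkpoints |
| `training` | Adam loop, exponential lr decay, similarity checkpointing |
| `metrics` | Dice, HD/HD95, standard errors, per-label reports |
| `mas` | atlas registration, ranking, majority / local-weighted voting |
| `experiments` | desk-scale studies used by tests and the acceptance script |
| `autodiff` | the numpy reverse-mode engine behind network and losses |
| `cli` | `morphcascade synth / train / register / segment / evaluate` |
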