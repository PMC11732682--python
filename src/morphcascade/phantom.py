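"""Synthetic multi-tissue 3-D brain phantoms and ground-truth deformations.

The phantoms are nested ellipsoidal regions mimicking the seven-class
anatomy used for fetal brain segmentation: an outer CSF shell, a cortical
grey-matter shell with a sinusoidal boundary perturbation, a white-matter
interior, two ventricle lobes, a thalamus core, and cerebellum / brain-stem
blobs.  A scalar ``age`` in [0, 1] scales the overall size (+-20 %) and the
cortical boundary irregularity, giving a monotone morphology axis that
emulates gestational age across a cohort.  No claim of anatomical realism is
made — the phantoms exist to exercise multi-class registration, fusion and
similarity machinery with known ground truth.

Ground-truth deformations are Gaussian-smoothed white-noise vector fields,
zero-mean per component, rescaled so the largest voxel displacement equals a
requested magnitude.  At the default scales they are smooth enough to be
fold-free (no negative Jacobian determinants).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi

from .transform import DisplacementField, warp_labels, warp_volume
from .volume_io import LabelMap, TISSUE_CLASSES, Volume, VolumeError

# per-class mean intensity (index = class id); background is 0
_CLASS_MEANS = np.array([0.0, 0.85, 0.45, 0.65, 0.95, 0.55, 0.75, 0.50])


@dataclass
class PhantomSpec:
    """Geometry, intensity-noise and seeding of one phantom."""

    size: int = 32
    n_tissues: int = 7
    age: float = 0.5
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.n_tissues <= 7):
            raise ValueError("n_tissues must be between 0 and 7")
        if not (0.0 <= self.age <= 1.0):
            raise ValueError("age must lie in [0, 1]")


@dataclass
class DeformationSpec:
    """Scale and smoothness of a random ground-truth field."""

    size: int = 32
    max_disp: float = 4.0
    smoothness_sigma: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.max_disp < 0:
            raise ValueError("max_disp must be non-negative")
        if self.smoothness_sigma <= 0:
            raise ValueError("smoothness_sigma must be positive")


def _region_labels(spec: PhantomSpec) -> np.ndarray:
    s = spec.size
    g = 0.8 + 0.4 * spec.age          # global scale, +-20 % around 1
    amp = 0.02 + 0.06 * spec.age      # cortical boundary irregularity
    c = (s - 1) / 2.0
    u = (np.indices((s, s, s), dtype=np.float64) - c) / (s / 2.0)
    rho = np.sqrt((u[0] / 0.75) ** 2 + (u[1] / 0.85) ** 2
                  + (u[2] / 0.70) ** 2) / g
    theta = np.arctan2(u[1], u[0])
    r = np.sqrt((u ** 2).sum(axis=0)) + 1e-9
    phi_ang = np.arccos(np.clip(u[2] / r, -1, 1))
    pert = amp * np.sin(6 * theta) * np.sin(4 * phi_ang)

    labels = np.zeros((s, s, s), dtype=np.uint8)
    head = rho < 1.0
    if spec.n_tissues >= 1:
        labels[head] = 1                                   # CSF shell
    if spec.n_tissues >= 2:
        labels[rho < 0.82 + pert] = 2                      # cortical GM
    if spec.n_tissues >= 3:
        labels[rho < 0.62 + 0.5 * pert] = 3                # white matter

    def ellipsoid(center, radii):
        d = ((u[0] - g * center[0]) / (g * radii[0])) ** 2 \
            + ((u[1] - g * center[1]) / (g * radii[1])) ** 2 \
            + ((u[2] - g * center[2]) / (g * radii[2])) ** 2
        return (d < 1.0) & head

    if spec.n_tissues >= 4:                                # ventricle lobes
        labels[ellipsoid((+0.18, 0.08, 0.05), (0.10, 0.22, 0.10))] = 4
        labels[ellipsoid((-0.18, 0.08, 0.05), (0.10, 0.22, 0.10))] = 4
    if spec.n_tissues >= 5:                                # cerebellum
        labels[ellipsoid((0.0, -0.52, -0.25), (0.26, 0.17, 0.17))] = 5
    if spec.n_tissues >= 6:                                # thalamus
        labels[ellipsoid((0.0, 0.02, -0.12), (0.15, 0.12, 0.12))] = 6
    if spec.n_tissues >= 7:                                # brain stem
        labels[ellipsoid((0.0, -0.18, -0.55), (0.10, 0.10, 0.28))] = 7
    return labels


def make_phantom(spec: PhantomSpec) -> tuple[Volume, LabelMap]:
    """Generate one phantom volume and its label map, deterministically."""
    if spec.size < 16:
        raise VolumeError("phantom size must be at least 16 voxels")
    labels = _region_labels(spec)
    data = _CLASS_MEANS[labels]
    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed, 0x9e3779b9])
        data = data + rng.normal(0.0, spec.noise_sd, data.shape)
    data = np.clip(data, 0.0, 1.0)
    lo, hi = data.min(), data.max()
    data = (data - lo) / (hi - lo)
    return Volume(data), LabelMap(labels, TISSUE_CLASSES)


def make_smooth_field(spec: DeformationSpec) -> DisplacementField:
    """Gaussian-smoothed zero-mean random field with a fixed peak magnitude."""
    s = spec.size
    if spec.max_disp == 0:
        return DisplacementField.zeros((s, s, s))
    rng = np.random.default_rng([spec.seed, 0x51ed2701])
    noise = rng.standard_normal((3, s, s, s))
    sig = spec.smoothness_sigma
    smooth = ndi.gaussian_filter(noise, sigma=(0, sig, sig, sig))
    smooth -= smooth.mean(axis=(1, 2, 3), keepdims=True)
    mags = np.linalg.norm(smooth, axis=0)
    peak = mags.max()
    if peak > 0:
        smooth *= spec.max_disp / peak
    return DisplacementField(smooth)


def make_pair(spec: PhantomSpec, dspec: DeformationSpec,
              ) -> tuple[Volume, Volume, LabelMap, LabelMap,
                         DisplacementField]:
    """A (fixed, moving) pair linked by a known smooth deformation.

    The moving image is the clean phantom warped by the truth field; noise
    is drawn independently for the fixed and moving volumes.  Registering
    moving -> fixed should recover (approximately) the inverse of the truth
    field.
    """
    if spec.size != dspec.size:
        raise VolumeError("phantom and deformation sizes must match")
    clean, labels = make_phantom(replace(spec, noise_sd=0.0))
    truth = make_smooth_field(dspec)
    moving_clean = warp_volume(clean, truth, interpolation="linear")
    moving_labels = warp_labels(labels, truth)

    def with_noise(vol: Volume, stream: int) -> Volume:
        if spec.noise_sd == 0:
            return vol
        rng = np.random.default_rng([spec.seed, dspec.seed, stream])
        data = vol.data + rng.normal(0.0, spec.noise_sd, vol.shape)
        return Volume(np.clip(data, 0.0, 1.0))

    fixed = with_noise(clean, 1)
    moving = with_noise(moving_clean, 2)
    return fixed, moving, labels, moving_labels, truth


def make_cohort(n: int, base_spec: PhantomSpec,
                age_range: tuple[float, float] = (0.1, 0.9),
                ) -> list[tuple[Volume, LabelMap, float]]:
    """n phantoms with ages spread evenly over `age_range` (an atlas library)."""
    if n < 2:
        raise ValueError("a cohort needs at least 2 members")
    lo, hi = age_range
    if not lo < hi:
        raise ValueError("age_range must be a non-empty interval")
    out = []
    for i, age in enumerate(np.linspace(lo, hi, n)):
        child_seed = int(np.random.SeedSequence(
            [base_spec.seed, i]).generate_state(1)[0])
        spec = replace(base_spec, age=float(age), seed=child_seed)
        vol, labels = make_phantom(spec)
        out.append((vol, labels, float(age)))
    return out
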