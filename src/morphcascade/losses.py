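"""Registration objectives: local NCC similarity and gradient smoothness.

The similarity term is the negative local (windowed) normalized
cross-correlation with a *squared* numerator, so each window contributes a
value in [0, 1] and perfect (anti-)correlation gives loss -1:

    CC = sum_p  cov_p(f, w)^2 / (var_p(f) * var_p(w))

with cov/var taken over the d^3 window around p.  The multi-resolution
variant averages this over several window sizes.  The regularizer is the
mean squared spatial gradient of the displacement field (all nine partial
derivatives, forward differences), so a translation costs nothing and a
uniform per-axis scaling by ``a`` costs exactly ``3 a^2``.

Both terms are means over voxels (not raw sums) so the weight ``lam``
keeps one meaning across image sizes.  The NCC is restricted to voxels
whose full window fits inside the domain.

All functions accept plain arrays / Volume / DisplacementField or autodiff
Tensors; with Tensor inputs they stay on the tape and are differentiable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .transform import DisplacementField
from .volume_io import Volume

DEFAULT_PATCH = 9
MULTI_RES_PATCHES = (5, 7, 9, 11)


@dataclass
class LossConfig:
    """Similarity windows, regularization weight and numeric guard."""

    patch_sizes: tuple[int, ...] = (DEFAULT_PATCH,)
    lam: float = 1.0
    epsilon: float = 1e-5

    def __post_init__(self):
        self.patch_sizes = tuple(int(d) for d in self.patch_sizes)
        for d in self.patch_sizes:
            if d % 2 == 0 or d < 3:
                raise ValueError(f"window size must be odd and >= 3, got {d}")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")


def _as_image_tensor(x) -> ad.Tensor:
    if isinstance(x, ad.Tensor):
        return x
    if isinstance(x, Volume):
        x = x.data
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("expected a 3-D image")
    return ad.Tensor(arr)


def _as_field_tensor(x) -> ad.Tensor:
    if isinstance(x, ad.Tensor):
        return x
    if isinstance(x, DisplacementField):
        x = x.vectors
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 4 or arr.shape[0] != 3:
        raise ValueError("expected a (3, D, H, W) field")
    return ad.Tensor(arr)


def local_ncc_t(fixed: ad.Tensor, warped: ad.Tensor, d: int,
                epsilon: float = 1e-5) -> ad.Tensor:
    """Tape version of the negative local NCC (squared numerator)."""
    if d % 2 == 0:
        raise ValueError("window size must be odd")
    if fixed.data.shape != warped.data.shape:
        raise ValueError("shape mismatch between fixed and warped images")
    if min(fixed.data.shape[-3:]) < d:
        raise ValueError("image smaller than the NCC window")
    n = float(d) ** 3
    r = d // 2
    sf = ad.box_sum(fixed, d)
    sw = ad.box_sum(warped, d)
    cross = ad.sub(ad.box_sum(ad.mul(fixed, warped), d),
                   ad.scale(ad.mul(sf, sw), 1.0 / n))
    var_f = ad.sub(ad.box_sum(ad.mul(fixed, fixed), d),
                   ad.scale(ad.mul(sf, sf), 1.0 / n))
    var_w = ad.sub(ad.box_sum(ad.mul(warped, warped), d),
                   ad.scale(ad.mul(sw, sw), 1.0 / n))
    denom = ad.mul(ad.add(var_f, ad.as_tensor(epsilon)),
                   ad.add(var_w, ad.as_tensor(epsilon)))
    cc = ad.div(ad.mul(cross, cross), denom)
    return ad.neg(ad.tmean(ad.crop3(cc, r)))


def local_ncc(fixed, warped, d: int = DEFAULT_PATCH,
              epsilon: float = 1e-5) -> float:
    """Negative local NCC between two images; -1 means perfect correlation."""
    return float(local_ncc_t(_as_image_tensor(fixed), _as_image_tensor(warped),
                             d, epsilon).data)


def multiscale_ncc_t(fixed: ad.Tensor, warped: ad.Tensor,
                     patch_sizes, epsilon: float = 1e-5) -> ad.Tensor:
    patch_sizes = tuple(patch_sizes)
    if not patch_sizes:
        raise ValueError("patch_sizes must be non-empty")
    terms = [local_ncc_t(fixed, warped, d, epsilon) for d in patch_sizes]
    total = terms[0]
    for t in terms[1:]:
        total = ad.add(total, t)
    return ad.scale(total, 1.0 / len(terms))


def multiscale_ncc(fixed, warped, patch_sizes=MULTI_RES_PATCHES,
                   epsilon: float = 1e-5) -> float:
    """Unweighted mean of the local NCC loss over several window sizes."""
    return float(multiscale_ncc_t(_as_image_tensor(fixed),
                                  _as_image_tensor(warped),
                                  patch_sizes, epsilon).data)


def smoothness_t(field: ad.Tensor) -> ad.Tensor:
    """Tape version of the mean squared field gradient."""
    if min(field.data.shape[-3:]) < 2:
        raise ValueError("field too small for finite differences")
    total = None
    for axis in (1, 2, 3):
        d = ad.fdiff(field, axis)
        # mean over (component, voxel); x3 turns it into a component sum
        term = ad.scale(ad.tmean(ad.mul(d, d)), 3.0)
        total = term if total is None else ad.add(total, term)
    return total


def smoothness(field) -> float:
    """Mean over voxels of the squared gradient norm of the field."""
    return float(smoothness_t(_as_field_tensor(field)).data)


def total_loss_t(fixed: ad.Tensor, warped: ad.Tensor, field: ad.Tensor,
                 cfg: LossConfig) -> ad.Tensor:
    sim = multiscale_ncc_t(fixed, warped, cfg.patch_sizes, cfg.epsilon)
    if cfg.lam == 0:
        return sim
    return ad.add(sim, ad.scale(smoothness_t(field), cfg.lam))


def total_loss(fixed, warped, field, cfg: LossConfig | None = None) -> float:
    """Similarity plus lam x smoothness, on the final warp and field only."""
    cfg = cfg or LossConfig()
    return float(total_loss_t(_as_image_tensor(fixed),
                              _as_image_tensor(warped),
                              _as_field_tensor(field), cfg).data)
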