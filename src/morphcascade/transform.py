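"""Dense displacement fields: warping, accumulation, composition, Jacobians.

A :class:`DisplacementField` stores one 3-vector per voxel of the fixed grid,
in voxel units.  Warping samples the moving image at ``x + phi(x)`` for every
fixed-grid voxel ``x``.  A cascade of partial fields is either *accumulated*
(voxel-wise sum, one interpolation of the original moving image) or
*composed* (functional composition, matching repeated warping).

Out-of-domain sample points are clamped to the nearest border voxel by
default ("replicate"); zero-fill is available via ``mode="constant"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage as ndi

from .volume_io import LabelMap, Volume, VolumeError


@dataclass
class DisplacementField:
    """Per-voxel displacement vectors (3, D, H, W) in voxel units."""

    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float32)
        if self.vectors.ndim != 4 or self.vectors.shape[0] != 3:
            raise VolumeError("field must have shape (3, D, H, W)")
        if not np.isfinite(self.vectors).all():
            raise VolumeError("field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[1:]

    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=0)

    @classmethod
    def zeros(cls, shape) -> "DisplacementField":
        return cls(np.zeros((3,) + tuple(shape), dtype=np.float32))


@dataclass
class JacobianReport:
    """Jacobian determinants of x -> x + phi(x) at interior voxels."""

    det_map: np.ndarray
    neg_fraction: float  # percent of interior voxels with det < 0

    def summary(self) -> dict:
        return {
            "neg_fraction_pct": float(self.neg_fraction),
            "det_min": float(self.det_map.min()),
            "det_max": float(self.det_map.max()),
            "det_mean": float(self.det_map.mean()),
        }


def _sample_coords(field: DisplacementField) -> np.ndarray:
    base = np.indices(field.shape, dtype=np.float64)
    return base + field.vectors


def warp_volume(moving: Volume, field: DisplacementField,
                interpolation: str = "linear",
                mode: str = "nearest") -> Volume:
    """Resample `moving` at x + phi(x); trilinear or nearest-neighbour."""
    if moving.shape != field.shape:
        raise VolumeError(
            f"shape mismatch: volume {moving.shape} vs field {field.shape}")
    if interpolation == "linear":
        order = 1
    elif interpolation == "nearest":
        order = 0
    else:
        raise ValueError(f"unknown interpolation mode: {interpolation!r}")
    data = ndi.map_coordinates(moving.data.astype(np.float64),
                               _sample_coords(field), order=order, mode=mode)
    return Volume(data, moving.spacing, moving.affine)


def warp_labels(moving_labels: LabelMap,
                field: DisplacementField) -> LabelMap:
    """Propagate labels along the field with nearest-neighbour sampling."""
    if moving_labels.shape != field.shape:
        raise VolumeError("shape mismatch between labels and field")
    data = ndi.map_coordinates(moving_labels.data, _sample_coords(field),
                               order=0, mode="nearest")
    return LabelMap(data, moving_labels.classes)


def _check_fields(fields: Sequence[DisplacementField]):
    fields = list(fields)
    if not fields:
        raise ValueError("need at least one field")
    shape = fields[0].shape
    for f in fields[1:]:
        if f.shape != shape:
            raise VolumeError("all fields must share one shape")
    return fields


def accumulate_fields(fields: Iterable[DisplacementField],
                      ) -> DisplacementField:
    """Voxel-wise vector sum of partial fields (the accumulation rule)."""
    fields = _check_fields(fields)
    total = np.zeros_like(fields[0].vectors)
    for f in fields:
        total = total + f.vectors
    return DisplacementField(total)


def compose_fields(fields: Iterable[DisplacementField]) -> DisplacementField:
    """Functional composition of partial fields in cascade order.

    With running composition c, appending phi gives
    ``c'(x) = phi(x + c(x)) + c(x)`` — i.e. the first field listed acts
    first.  Equals accumulation when the fields are spatially constant.
    """
    fields = _check_fields(fields)
    comp = np.zeros_like(fields[0].vectors, dtype=np.float64)
    base = np.indices(fields[0].shape, dtype=np.float64)
    for f in fields:
        if comp.any():
            coords = base + comp
            sampled = np.stack([
                ndi.map_coordinates(f.vectors[c].astype(np.float64), coords,
                                    order=1, mode="nearest")
                for c in range(3)])
        else:
            sampled = f.vectors.astype(np.float64)
        comp = comp + sampled
    return DisplacementField(comp)


def jacobian_report(field: DisplacementField) -> JacobianReport:
    """det(I + grad phi) by central differences at interior voxels."""
    if min(field.shape) < 3:
        raise VolumeError("grid too small for central differences")
    v = field.vectors.astype(np.float64)
    interior = (slice(1, -1),) * 3
    jac = np.empty((3, 3) + tuple(s - 2 for s in field.shape))
    for i in range(3):
        grads = np.gradient(v[i], axis=(0, 1, 2))
        for j in range(3):
            jac[i, j] = grads[j][interior]
        jac[i, i] += 1.0
    det = (jac[0, 0] * (jac[1, 1] * jac[2, 2] - jac[1, 2] * jac[2, 1])
           - jac[0, 1] * (jac[1, 0] * jac[2, 2] - jac[1, 2] * jac[2, 0])
           + jac[0, 2] * (jac[1, 0] * jac[2, 1] - jac[1, 1] * jac[2, 0]))
    neg = 100.0 * float((det < 0).mean())
    return JacobianReport(det_map=det, neg_fraction=neg)


# ------------------------------------------------------------------ NIfTI IO

def write_field(field: DisplacementField, path) -> None:
    """Store as 4-D NIfTI, last axis = vector component (x, y, z), voxels."""
    arr = np.moveaxis(field.vectors, 0, -1).astype(np.float32)
    nib.save(nib.Nifti1Image(arr, np.eye(4)), str(path))


def read_field(path) -> DisplacementField:
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise VolumeError("field file must be 4-D with 3 components")
    return DisplacementField(np.moveaxis(arr, -1, 0))


def write_jacobian_report(report: JacobianReport, det_path, json_path) -> None:
    nib.save(nib.Nifti1Image(report.det_map.astype(np.float32), np.eye(4)),
             str(det_path))
    with open(json_path, "w") as fh:
        json.dump(report.summary(), fh, indent=2)
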