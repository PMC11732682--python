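"""Volumes, label maps, NIfTI I/O and the standard preprocessing chain.

Volumes are single-channel 3-D intensity grids; label maps are integer grids
over a fixed class set (0 = background plus seven tissue classes: CSF,
cortical grey matter, white matter, ventricles, cerebellum, thalamus, brain
stem).  Preprocessing follows the usual recipe for skull-stripped brain
volumes: crop to the foreground bounding box, resample to a cube, rescale
intensities to [0, 1].
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage as ndi

#: label ids: 0 background, then CSF, CGM, WM, VTC, CRB, THA, BS
TISSUE_CLASSES: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6, 7)
TISSUE_NAMES = ("BG", "CSF", "CGM", "WM", "VTC", "CRB", "THA", "BS")


class VolumeError(ValueError):
    """Raised for malformed or degenerate volume inputs."""


@dataclass
class Volume:
    """A 3-D scalar intensity grid with voxel spacing and world affine."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise VolumeError(f"not a 3-D volume (ndim={self.data.ndim})")
        if min(self.data.shape) < 2:
            raise VolumeError("every axis must have at least 2 voxels")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelMap:
    """Integer class labels on the same grid as a companion Volume."""

    data: np.ndarray
    classes: tuple[int, ...] = TISSUE_CLASSES

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeError("label map must be 3-D")
        if not np.isin(self.data, self.classes).all():
            raise VolumeError("label map contains values outside its classes")
        self.data = self.data.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def present_classes(self) -> tuple[int, ...]:
        return tuple(int(c) for c in np.unique(self.data))


def read_volume(path: str | os.PathLike) -> Volume:
    """Load a NIfTI file as a :class:`Volume` (data, spacing, affine)."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several header error types
        raise VolumeError(f"unreadable NIfTI header in {path}: {exc}") from exc
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 3:
        raise VolumeError(f"not a 3-D volume: {path} has ndim={arr.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(arr.astype(np.float32), spacing, np.array(img.affine))


def write_volume(vol: Volume, path: str | os.PathLike) -> None:
    affine = vol.affine if vol.affine is not None else np.diag(
        list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_labels(path: str | os.PathLike,
                classes: tuple[int, ...] = TISSUE_CLASSES) -> LabelMap:
    vol = read_volume(path)
    return LabelMap(np.rint(vol.data).astype(np.uint8), classes)


def write_labels(labels: LabelMap, path: str | os.PathLike,
                 spacing=(1.0, 1.0, 1.0), affine=None) -> None:
    if affine is None:
        affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(labels.data.astype(np.uint8), affine)
    nib.save(img, str(path))


def crop_to_foreground(vol: Volume, labels: LabelMap | None = None,
                       margin: int = 2, threshold: float = 0.0,
                       ) -> tuple[Volume, LabelMap | None]:
    """Crop to the bounding box of voxels with intensity > threshold.

    The box is expanded by `margin` voxels per side and clipped to the grid.
    The default threshold of 0 matches skull-stripped volumes where all
    non-brain voxels are exactly zero.
    """
    fg = vol.data > threshold
    if not fg.any():
        raise VolumeError("cannot crop an all-background volume")
    slices = []
    for ax in range(3):
        proj = fg.any(axis=tuple(i for i in range(3) if i != ax))
        idx = np.where(proj)[0]
        lo = max(int(idx[0]) - margin, 0)
        hi = min(int(idx[-1]) + 1 + margin, vol.data.shape[ax])
        slices.append(slice(lo, hi))
    box = tuple(slices)
    out = Volume(vol.data[box], vol.spacing, vol.affine)
    out_labels = None
    if labels is not None:
        if labels.shape != vol.shape:
            raise VolumeError("labels do not match the volume shape")
        out_labels = LabelMap(labels.data[box], labels.classes)
    return out, out_labels


def _cube_coords(shape, n):
    """Sampling coordinates for an aligned-endpoint resize to n^3."""
    axes = [np.linspace(0.0, s - 1.0, n) for s in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"))


def resize_to_cube(vol: Volume, n: int = 128, labels: LabelMap | None = None,
                   ) -> tuple[Volume, LabelMap | None]:
    """Resample to n x n x n: trilinear for intensities, nearest for labels.

    Sample points include both endpoints on each axis, so resizing to the
    current (cubic) shape is an exact identity.
    """
    if n < 2:
        raise VolumeError("target side length must be at least 2")
    coords = _cube_coords(vol.shape, n)
    data = ndi.map_coordinates(vol.data, coords, order=1, mode="nearest")
    scale = [(s - 1.0) / (n - 1.0) for s in vol.shape]
    spacing = tuple(sp * sc for sp, sc in zip(vol.spacing, scale))
    out = Volume(data, spacing, vol.affine)
    out_labels = None
    if labels is not None:
        if labels.shape != vol.shape:
            raise VolumeError("labels do not match the volume shape")
        ldata = ndi.map_coordinates(labels.data, coords, order=0,
                                    mode="nearest")
        out_labels = LabelMap(ldata, labels.classes)
    return out, out_labels


def normalize_intensity(vol: Volume) -> Volume:
    """Affinely rescale intensities so that min = 0 and max = 1."""
    lo = float(vol.data.min())
    hi = float(vol.data.max())
    if hi == lo:
        raise VolumeError("cannot normalize a constant volume")
    return Volume((vol.data - lo) / (hi - lo), vol.spacing, vol.affine)


def preprocess(vol: Volume, labels: LabelMap | None = None, n: int = 128,
               margin: int = 2) -> tuple[Volume, LabelMap | None]:
    """crop -> resize -> normalize, the standard chain before registration."""
    vol, labels = crop_to_foreground(vol, labels, margin=margin)
    vol, labels = resize_to_cube(vol, n, labels)
    return normalize_intensity(vol), labels
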