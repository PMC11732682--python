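"""Multi-atlas segmentation: register, select, propagate, fuse.

Every atlas is registered to the target with the cascade model and its
labels are propagated along the final field (nearest-neighbour).  Warped
atlases are ranked by whole-volume similarity to the target (NCC by
default; MSE and SSIM available), the best ``n_select`` are kept, and their
propagated labels are fused either by majority voting (MV) or by local
weighted voting (LWV).  LWV weights atlas k's vote at voxel i by

    w_k,i = |m_k(i)|^g

where m_k(i) is the mean local similarity (windowed NCC, window edge d)
between warped atlas k and the target around i, clamped at 0 from below,
and g is a gain exponent.  Ties always break toward the lowest class id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.metrics import structural_similarity

from .network import CascadeModel
from .transform import DisplacementField, warp_labels
from .volume_io import LabelMap, Volume, VolumeError

SELECTION_METRICS = ("ncc", "mse", "ssim")


@dataclass
class AtlasSet:
    """Annotated reference volumes; metadata is free-form (e.g. {'age': x})."""

    entries: list[tuple[Volume, LabelMap, dict]]

    def __post_init__(self):
        if not self.entries:
            raise ValueError("atlas set is empty")
        classes = self.entries[0][1].classes
        for _, lab, _ in self.entries:
            if lab.classes != classes:
                raise VolumeError("atlases must share one class set")

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_cohort(cls, cohort) -> "AtlasSet":
        return cls([(v, l, {"age": a}) for v, l, a in cohort])


@dataclass
class FusionConfig:
    """Atlas selection and label-fusion settings."""

    n_select: int = 10
    selection_metric: str = "ncc"
    fusion: str = "lwv"           # "lwv" or "mv"
    window: int = 9               # LWV local-similarity window edge d
    gain: float = 2.0             # LWV exponent g

    def __post_init__(self):
        self.selection_metric = self.selection_metric.lower()
        if self.selection_metric not in SELECTION_METRICS:
            raise ValueError(f"unknown selection metric: "
                             f"{self.selection_metric!r}")
        self.fusion = self.fusion.lower()
        if self.fusion not in ("mv", "lwv"):
            raise ValueError(f"unknown fusion mode: {self.fusion!r}")
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window must be odd and >= 3")
        if self.gain < 0:
            raise ValueError("gain must be non-negative")
        if self.n_select < 1:
            raise ValueError("n_select must be >= 1")


def register_atlases(target: Volume, atlases: AtlasSet, model: CascadeModel,
                     ) -> list[tuple[Volume, LabelMap, DisplacementField]]:
    """Register every atlas (moving) to the target (fixed); propagate labels."""
    out = []
    for vol, labels, _ in atlases.entries:
        if vol.shape != target.shape:
            raise VolumeError("atlas and target shapes differ")
        warped, _, final = model.register(vol, target)
        out.append((warped, warp_labels(labels, final), final))
    return out


def global_ncc(a: np.ndarray, b: np.ndarray,
               foreground: np.ndarray | None = None) -> float:
    """Whole-volume Pearson correlation, optionally restricted to a mask."""
    if foreground is not None:
        a, b = a[foreground], b[foreground]
    a = a.astype(np.float64).ravel() - a.mean()
    b = b.astype(np.float64).ravel() - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def rank_atlases(target: Volume, warped: list[Volume],
                 metric: str = "ncc") -> tuple[list[int], list[float]]:
    """Order warped atlases best-first by similarity to the target.

    Similarity is computed on the target's foreground (nonzero) voxels for
    NCC and MSE; SSIM uses the full volume (it is window-based already).
    Returns (indices, scores) with scores aligned to the returned order.
    """
    metric = metric.lower()
    if metric not in SELECTION_METRICS:
        raise ValueError(f"unknown selection metric: {metric!r}")
    if not warped:
        raise ValueError("no warped atlases to rank")
    fg = target.data > 0
    if not fg.any():
        fg = None
    scores = []
    for w in warped:
        if metric == "ncc":
            scores.append(global_ncc(target.data, w.data, fg))
        elif metric == "mse":
            a = target.data[fg] if fg is not None else target.data
            b = w.data[fg] if fg is not None else w.data
            scores.append(float(np.mean((a.astype(np.float64) - b) ** 2)))
        else:
            rng = float(target.data.max() - target.data.min()) or 1.0
            scores.append(float(structural_similarity(
                target.data, w.data, data_range=rng)))
    order = np.argsort(scores, kind="stable")
    if metric != "mse":          # higher is better except for MSE
        order = order[::-1]
    return [int(i) for i in order], [scores[i] for i in order]


def _one_hot_scores(propagated: list[LabelMap],
                    weights: list[np.ndarray] | None) -> np.ndarray:
    classes = propagated[0].classes
    shape = propagated[0].shape
    scores = np.zeros((len(classes),) + shape, dtype=np.float64)
    for k, lab in enumerate(propagated):
        if lab.shape != shape:
            raise VolumeError("propagated label maps must share a shape")
        w = 1.0 if weights is None else weights[k]
        for ci, c in enumerate(classes):
            m = lab.data == c
            if np.isscalar(w):
                scores[ci][m] += w
            else:
                scores[ci][m] += w[m]
    return scores


def _argmax_lowest_tie(scores: np.ndarray, classes) -> np.ndarray:
    # np.argmax returns the first (lowest) index on ties; classes are ordered
    idx = scores.argmax(axis=0)
    return np.asarray(classes, dtype=np.uint8)[idx]


def majority_vote(propagated: list[LabelMap]) -> LabelMap:
    """Per-voxel modal label; ties break toward the lowest class id."""
    if not propagated:
        raise ValueError("no label maps to fuse")
    scores = _one_hot_scores(propagated, None)
    return LabelMap(_argmax_lowest_tie(scores, propagated[0].classes),
                    propagated[0].classes)


def _local_similarity(target: np.ndarray, warped: np.ndarray, d: int,
                      epsilon: float = 1e-5) -> np.ndarray:
    """Signed windowed NCC map (unsquared numerator), same shape as inputs."""
    t = target.astype(np.float64)
    w = warped.astype(np.float64)
    n = float(d) ** 3
    kernel = np.ones(d)

    def box(x):
        for ax in range(3):
            x = ndi.correlate1d(x, kernel, axis=ax, mode="constant")
        return x

    st, sw = box(t), box(w)
    cross = box(t * w) - st * sw / n
    var_t = np.maximum(box(t * t) - st * st / n, 0.0)
    var_w = np.maximum(box(w * w) - sw * sw / n, 0.0)
    return cross / (np.sqrt(var_t * var_w) + epsilon)


def local_weighted_vote(target: Volume, warped: list[Volume],
                        propagated: list[LabelMap],
                        cfg: FusionConfig | None = None) -> LabelMap:
    """Fuse labels weighting each atlas's vote by local similarity^gain."""
    cfg = cfg or FusionConfig()
    if len(warped) != len(propagated):
        raise ValueError("warped and propagated lists must align")
    if not propagated:
        raise ValueError("no label maps to fuse")
    weights = []
    for w in warped:
        m = _local_similarity(target.data, w.data, cfg.window)
        m = np.clip(m, 0.0, None)       # |m|^g with negatives floored at 0
        weights.append(m ** cfg.gain)
    scores = _one_hot_scores(propagated, weights)
    return LabelMap(_argmax_lowest_tie(scores, propagated[0].classes),
                    propagated[0].classes)


def segment(target: Volume, atlases: AtlasSet, model: CascadeModel,
            cfg: FusionConfig | None = None) -> tuple[LabelMap, dict]:
    """Full pipeline: register -> rank -> select top-n -> fuse.

    Returns the fused label map and a provenance record with the ranked
    scores and the selected atlas indices.
    """
    cfg = cfg or FusionConfig()
    if cfg.n_select > len(atlases):
        raise ValueError("n_select exceeds the atlas count")
    registered = register_atlases(target, atlases, model)
    warped = [r[0] for r in registered]
    order, scores = rank_atlases(target, warped, cfg.selection_metric)
    keep = order[:cfg.n_select]
    sel_warped = [warped[i] for i in keep]
    sel_labels = [registered[i][1] for i in keep]
    if cfg.fusion == "mv":
        fused = majority_vote(sel_labels)
    else:
        fused = local_weighted_vote(target, sel_warped, sel_labels, cfg)
    provenance = {
        "selection_metric": cfg.selection_metric,
        "fusion": cfg.fusion,
        "ranked_indices": order,
        "ranked_scores": scores,
        "selected_indices": keep,
        "n_select": cfg.n_select,
        "window": cfg.window,
        "gain": cfg.gain,
    }
    return fused, provenance
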