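"""Cascaded registration networks with deformation-field accumulation.

Each cascade is a convolutional encoder-decoder that consumes the 2-channel
concatenation of the (current) warped moving image and the fixed image and
emits a dense partial displacement field.  The cascade recursion:

    phi_1 = net_1(X_mv, X_fx)
    X_wp,k = X_mv  o  sum_{i<=k} phi_i        (accumulation mode)
    phi_{k+1} = net_{k+1}(X_wp,k, X_fx)

so the *original* moving image is interpolated exactly once per step and the
final field is the voxel-wise sum of the partial fields.  The alternative
(no-accumulation) mode warps the previous warped image by each new partial
field, and the final field is the functional composition of the partials.

The backbone is a "contracted" design: wider hidden feature maps, and no
convolution at full image resolution — the field is predicted at half
resolution and trilinearly upsampled (vectors scaled by 2 to stay in voxel
units).  The field-emitting convolution is zero-initialized so an untrained
cascade is exactly the identity map.  Cascades do not share parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field as dfield

import numpy as np

from . import autodiff as ad
from .losses import LossConfig
from .transform import DisplacementField
from .volume_io import Volume, VolumeError


@dataclass
class BackboneConfig:
    """Channel plan of one encoder-decoder cascade."""

    enc_channels: tuple[int, ...] = (8, 16, 16)
    dec_channels: tuple[int, ...] = (16, 8)
    emit_at_half_resolution: bool = True
    leaky_slope: float = 0.2
    kernel: int = 3

    def __post_init__(self):
        self.enc_channels = tuple(int(c) for c in self.enc_channels)
        self.dec_channels = tuple(int(c) for c in self.dec_channels)
        if any(c < 1 for c in self.enc_channels + self.dec_channels):
            raise ValueError("channel counts must be >= 1")
        if len(self.dec_channels) != len(self.enc_channels) - 1:
            raise ValueError("need len(dec_channels) == len(enc_channels) - 1")

    @property
    def levels(self) -> int:
        return len(self.enc_channels)


@dataclass
class CascadeConfig:
    """Number of cascades, recursion mode and shared backbone plan."""

    n_cascades: int = 3
    accumulate: bool = True
    backbone: BackboneConfig = dfield(default_factory=BackboneConfig)
    image_size: int = 32

    def __post_init__(self):
        if self.n_cascades < 1:
            raise ValueError("n_cascades must be >= 1")
        if isinstance(self.backbone, dict):
            self.backbone = BackboneConfig(**self.backbone)
        div = 2 ** self.backbone.levels
        if self.image_size % div:
            raise ValueError(
                f"image size {self.image_size} must be divisible by {div} "
                f"({self.backbone.levels} downsampling levels)")


def _he_conv(rng, cout, cin, k, dtype=np.float32):
    fan_in = cin * k ** 3
    w = rng.standard_normal((cout, cin, k, k, k)) * np.sqrt(2.0 / fan_in)
    return w.astype(dtype)


def init_backbone_params(cfg: BackboneConfig, rng) -> dict[str, ad.Tensor]:
    """Fresh parameters; the flow-emitting convolution starts at zero."""
    k = cfg.kernel
    params: dict[str, ad.Tensor] = {}
    cin = 2
    for i, c in enumerate(cfg.enc_channels):
        params[f"enc{i}.w"] = ad.parameter(_he_conv(rng, c, cin, k))
        params[f"enc{i}.b"] = ad.parameter(np.zeros(c, dtype=np.float32))
        cin = c
    feat = cfg.enc_channels[-1]
    for i, c in enumerate(cfg.dec_channels):
        skip = cfg.enc_channels[-2 - i]
        params[f"dec{i}.w"] = ad.parameter(_he_conv(rng, c, feat + skip, k))
        params[f"dec{i}.b"] = ad.parameter(np.zeros(c, dtype=np.float32))
        feat = c
    if not cfg.emit_at_half_resolution:
        # an extra full-resolution stage consuming the raw 2-channel input
        c = cfg.dec_channels[-1]
        params["full.w"] = ad.parameter(_he_conv(rng, c, feat + 2, k))
        params["full.b"] = ad.parameter(np.zeros(c, dtype=np.float32))
        feat = c
    params["flow.w"] = ad.parameter(
        np.zeros((3, feat, k, k, k), dtype=np.float32))
    params["flow.b"] = ad.parameter(np.zeros(3, dtype=np.float32))
    return params


def backbone_forward(params: dict[str, ad.Tensor], moving: ad.Tensor,
                     fixed: ad.Tensor, cfg: BackboneConfig) -> ad.Tensor:
    """Predict a (3, D, H, W) displacement field from a pair of images.

    `moving` and `fixed` are (1, D, H, W) tensors on the tape.
    """
    size = moving.data.shape[-1]
    div = 2 ** cfg.levels
    if size % div:
        raise VolumeError(
            f"input side {size} not divisible by {div} "
            f"(required by {cfg.levels} encoder levels)")
    x = ad.concat([moving, fixed], axis=0)
    skips = []
    feat = x
    for i in range(cfg.levels):
        feat = ad.leaky_relu(
            ad.conv3d(feat, params[f"enc{i}.w"], params[f"enc{i}.b"],
                      stride=2, pad=cfg.kernel // 2),
            cfg.leaky_slope)
        skips.append(feat)
    for i in range(len(cfg.dec_channels)):
        feat = ad.upsample2_linear(feat)
        feat = ad.concat([feat, skips[-2 - i]], axis=0)
        feat = ad.leaky_relu(
            ad.conv3d(feat, params[f"dec{i}.w"], params[f"dec{i}.b"],
                      stride=1, pad=cfg.kernel // 2),
            cfg.leaky_slope)
    if cfg.emit_at_half_resolution:
        flow = ad.conv3d(feat, params["flow.w"], params["flow.b"],
                         stride=1, pad=cfg.kernel // 2)
        # x2 upsampling doubles the voxel pitch, so vectors scale by 2
        flow = ad.scale(ad.upsample2_linear(flow), 2.0)
    else:
        feat = ad.upsample2_linear(feat)
        feat = ad.concat([feat, x], axis=0)
        feat = ad.leaky_relu(
            ad.conv3d(feat, params["full.w"], params["full.b"],
                      stride=1, pad=cfg.kernel // 2),
            cfg.leaky_slope)
        flow = ad.conv3d(feat, params["flow.w"], params["flow.b"],
                         stride=1, pad=cfg.kernel // 2)
    return flow


class CascadeModel:
    """A stack of independently parameterized registration cascades."""

    def __init__(self, cfg: CascadeConfig, seed: int = 0,
                 params: list[dict[str, ad.Tensor]] | None = None):
        self.cfg = cfg
        if params is None:
            rng = np.random.default_rng([seed, 0xcab0c1])
            params = [init_backbone_params(cfg.backbone, rng)
                      for _ in range(cfg.n_cascades)]
        self.params = params
        self.moving_interpolations = 0  # instrumentation for warp counting

    def parameters(self) -> list[ad.Tensor]:
        return [t for p in self.params for t in p.values()]

    def forward(self, moving: ad.Tensor, fixed: ad.Tensor,
                ) -> tuple[ad.Tensor, list[ad.Tensor], ad.Tensor]:
        """Run the cascade; returns (warped, partial fields, final field)."""
        partials: list[ad.Tensor] = []
        warped = moving
        running = None
        for k, p in enumerate(self.params):
            phi = backbone_forward(p, warped, fixed, self.cfg.backbone)
            partials.append(phi)
            if self.cfg.accumulate:
                running = phi if running is None else ad.add(running, phi)
                warped = ad.warp3d(moving, running)
                self.moving_interpolations += 1
            else:
                warped = ad.warp3d(warped, phi)
        if self.cfg.accumulate:
            final = running
        else:
            final = _compose_tape(partials)
        return warped, partials, final

    def register(self, moving: Volume, fixed: Volume,
                 ) -> tuple[Volume, list[DisplacementField],
                            DisplacementField]:
        """Numpy-level registration of one pair (no gradient use)."""
        if moving.shape != fixed.shape:
            raise VolumeError("moving and fixed shapes differ")
        mt = ad.Tensor(moving.data[None].astype(np.float32))
        ft = ad.Tensor(fixed.data[None].astype(np.float32))
        warped, partials, final = self.forward(mt, ft)
        return (Volume(warped.data[0], fixed.spacing, fixed.affine),
                [DisplacementField(p.data) for p in partials],
                DisplacementField(final.data))


def _compose_tape(partials: list[ad.Tensor]) -> ad.Tensor:
    """Functional composition of partial fields on the tape (first acts first)."""
    comp = partials[0]
    for phi in partials[1:]:
        comp = ad.add(ad.warp3d(phi, comp), comp)
    return comp


# ---------------------------------------------------------------- checkpoints

def save_checkpoint(path, model: CascadeModel, loss_cfg: LossConfig,
                    epoch: int = 0, val_loss: float = float("nan")) -> None:
    """Parameters plus full configuration in one .npz file."""
    meta = {
        "cascade": {**asdict(model.cfg), "backbone": asdict(model.cfg.backbone)},
        "loss": {"patch_sizes": list(loss_cfg.patch_sizes),
                 "lam": loss_cfg.lam, "epsilon": loss_cfg.epsilon},
        "epoch": epoch,
        "val_loss": val_loss,
    }
    arrays = {f"c{k}.{name}": t.data
              for k, p in enumerate(model.params) for name, t in p.items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[CascadeModel, LossConfig, dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        ccfg = dict(meta["cascade"])
        ccfg["backbone"] = BackboneConfig(**ccfg["backbone"])
        cfg = CascadeConfig(**ccfg)
        params = [dict() for _ in range(cfg.n_cascades)]
        for key in z.files:
            if key == "__meta__":
                continue
            ck, name = key.split(".", 1)
            params[int(ck[1:])][name] = ad.parameter(z[key])
    model = CascadeModel(cfg, params=params)
    lcfg = meta["loss"]
    loss_cfg = LossConfig(tuple(lcfg["patch_sizes"]), lcfg["lam"],
                          lcfg["epsilon"])
    return model, loss_cfg, {"epoch": meta["epoch"],
                             "val_loss": meta["val_loss"]}
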