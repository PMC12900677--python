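"""The dual-path super-resolution network.

Architecture: a single 3x3 conv lifts the LR image to a ``d``-channel
feature map F0; two parallel paths process it at LR resolution — a
transformer path of residual Swin-style blocks (windowed multi-head
self-attention with alternating cyclic shifts, pre-norm MLPs, a trailing
3x3 conv and block residual) for global context, and a CNN path of
residual channel-attention blocks (conv-ReLU-conv with squeeze/excite
gating) for local vascular detail.  The paths are fused by a multi-scale
module (channel concat, pooled pyramid, per-level 1x1 convs, bilinear
re-expansion and sum) and reconstructed by sub-pixel convolution stages,
with the bicubically upsampled input added back as a global residual so an
untrained network starts exactly at the bicubic baseline (the final
reconstruction conv is zero-initialised).

Design choices where the architecture family leaves freedom: Swin-style
relative position bias and pre-norm layer placement; channel-attention
reduction 16; MLP ratio 2; fusion pyramid {x1, x1/2, x1/4}; bicubic global
residual; no patch tokenisation (windows partition the conv feature map).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .errors import ConfigError, ContractError
from .imaging import resize_bicubic, validate_image
from .nn import Conv2d, LayerNorm, Linear, Module, Parameter, Tensor, concat, trunc_normal


@dataclass(frozen=True)
class ModelConfig:
    scale: int = 2
    feature_dim: int = 180
    n_rstb: int = 6
    stl_per_rstb: int = 6
    n_rcab: int = 8
    window: int = 8
    heads: int = 8
    mlp_ratio: float = 2.0
    ca_reduction: int = 16
    fusion_scales: int = 3
    in_channels: int = 3

    def __post_init__(self):
        if self.scale not in (2, 4):
            raise ConfigError("scale must be 2 or 4")
        if self.feature_dim % self.heads:
            raise ConfigError("feature_dim must be divisible by heads")
        if self.feature_dim % self.ca_reduction:
            raise ConfigError("feature_dim must be divisible by ca_reduction")
        if self.window < 2:
            raise ConfigError("window must be >= 2")
        if min(self.n_rstb, self.stl_per_rstb, self.n_rcab,
               self.fusion_scales) < 1:
            raise ConfigError("all block counts must be >= 1")
        if self.in_channels not in (1, 3):
            raise ConfigError("in_channels must be 1 or 3")

    @property
    def head_dim(self) -> int:
        return self.feature_dim // self.heads

    @classmethod
    def tiny(cls, scale: int = 2, in_channels: int = 3) -> "ModelConfig":
        """Desk-scale preset used for CPU training and tests."""
        return cls(scale=scale, feature_dim=16, n_rstb=1, stl_per_rstb=2,
                   n_rcab=2, window=4, heads=2, mlp_ratio=2.0,
                   ca_reduction=4, fusion_scales=2, in_channels=in_channels)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


# ------------------------------------------------------------------ blocks

class WindowAttention(Module):
    """Multi-head self-attention within (optionally shifted) square windows."""

    def __init__(self, d: int, window: int, heads: int, rng: np.random.Generator):
        self.qkv = Linear(d, 3 * d, rng)
        self.proj = Linear(d, d, rng)
        ws = window
        self.bias_table = Parameter(
            trunc_normal(rng, ((2 * ws - 1) ** 2, heads), 0.02))
        self.window = ws
        self.heads = heads
        self.d = d
        coords = np.stack(np.mgrid[0:ws, 0:ws]).reshape(2, -1)  # (2, L)
        rel = coords[:, :, None] - coords[:, None, :]            # (2, L, L)
        rel = rel + (ws - 1)
        self._bias_idx = (rel[0] * (2 * ws - 1) + rel[1]).ravel()

    def __call__(self, x: Tensor, shift: int, mask: np.ndarray | None) -> Tensor:
        n, hp, wp, c = x.shape
        ws, heads = self.window, self.heads
        dk = c // heads
        if shift:
            x = x.roll((-shift, -shift), axis=(1, 2))
        nh, nw = hp // ws, wp // ws
        xw = x.reshape(n, nh, ws, nw, ws, c).transpose(0, 1, 3, 2, 4, 5)
        xw = xw.reshape(n * nh * nw, ws * ws, c)
        b, L = n * nh * nw, ws * ws
        qkv = self.qkv(xw).reshape(b, L, 3, heads, dk).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]          # (b, heads, L, dk)
        attn = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dk))
        bias = self.bias_table.take0(self._bias_idx)
        bias = bias.reshape(L, L, heads).transpose(2, 0, 1)
        attn = attn + bias
        if mask is not None:
            attn = attn.reshape(n, nh * nw, heads, L, L) + Tensor(
                mask[None, :, None, :, :])
            attn = attn.reshape(b, heads, L, L)
        attn = attn.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, L, c)
        out = self.proj(out)
        out = out.reshape(n, nh, nw, ws, ws, c).transpose(0, 1, 3, 2, 4, 5)
        out = out.reshape(n, hp, wp, c)
        if shift:
            out = out.roll((shift, shift), axis=(1, 2))
        return out


def shift_attention_mask(hp: int, wp: int, window: int, shift: int) -> np.ndarray:
    """Swin-style additive mask (-100 across region boundaries) for shifted
    windows, shape (n_windows, L, L)."""
    img = np.zeros((hp, wp))
    cnt = 0
    spans = (slice(0, -window), slice(-window, -shift), slice(-shift, None))
    for hs in spans:
        for vs in spans:
            img[hs, vs] = cnt
            cnt += 1
    nh, nw = hp // window, wp // window
    ids = img.reshape(nh, window, nw, window).transpose(0, 2, 1, 3)
    ids = ids.reshape(nh * nw, window * window)
    return np.where(ids[:, None, :] != ids[:, :, None], -100.0, 0.0)


class STL(Module):
    """Swin transformer layer: pre-norm window attention + pre-norm MLP."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        d = cfg.feature_dim
        hidden = int(d * cfg.mlp_ratio)
        self.norm1 = LayerNorm(d)
        self.attn = WindowAttention(d, cfg.window, cfg.heads, rng)
        self.norm2 = LayerNorm(d)
        self.fc1 = Linear(d, hidden, rng)
        self.fc2 = Linear(hidden, d, rng)

    def __call__(self, x: Tensor, shift: int, mask: np.ndarray | None) -> Tensor:
        x = x + self.attn(self.norm1(x), shift, mask)
        return x + self.fc2(self.fc1(self.norm2(x)).gelu())


class RSTB(Module):
    """Residual Swin transformer block: STL stack + 3x3 conv + residual."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.stls = [STL(cfg, rng) for _ in range(cfg.stl_per_rstb)]
        self.conv = Conv2d(cfg.feature_dim, cfg.feature_dim, 3, rng)
        self.window = cfg.window

    def __call__(self, x: Tensor) -> Tensor:
        # x is NCHW with spatial dims already padded to window multiples
        t = x.transpose(0, 2, 3, 1)
        _, hp, wp, _ = t.shape
        shift = self.window // 2
        mask = shift_attention_mask(hp, wp, self.window, shift)
        for i, stl in enumerate(self.stls):
            s = shift if i % 2 else 0
            t = stl(t, s, mask if s else None)
        return x + self.conv(t.transpose(0, 3, 1, 2))


class ChannelAttention(Module):
    """Squeeze/excite gate: sigmoid(W2 ReLU(W1 GAP(F))) applied per channel."""

    def __init__(self, d: int, r: int, rng: np.random.Generator):
        self.fc1 = Linear(d, d // r, rng)
        self.fc2 = Linear(d // r, d, rng)

    def gate(self, x: Tensor) -> Tensor:
        a = x.mean(axis=(2, 3))                  # GAP -> (N, C)
        return self.fc2(self.fc1(a).relu()).sigmoid()

    def __call__(self, x: Tensor) -> Tensor:
        n, c = x.shape[:2]
        return x * self.gate(x).reshape(n, c, 1, 1)


class RCAB(Module):
    """Residual channel-attention block: conv-ReLU-conv, gated, + residual."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        d = cfg.feature_dim
        self.conv1 = Conv2d(d, d, 3, rng)
        self.conv2 = Conv2d(d, d, 3, rng)
        self.ca = ChannelAttention(d, cfg.ca_reduction, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return x + self.ca(self.conv2(self.conv1(x).relu()))


class Fusion(Module):
    """Multi-scale fusion: concat both paths, pooled pyramid {1, 1/2, ...},
    per-level 1x1 conv back to d channels, bilinear re-expansion, sum."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        d = cfg.feature_dim
        self.convs = [Conv2d(2 * d, d, 1, rng) for _ in range(cfg.fusion_scales)]
        self.n_scales = cfg.fusion_scales

    def __call__(self, ft: Tensor, fc: Tensor) -> Tensor:
        if ft.shape != fc.shape:
            raise ContractError("fusion: path shapes differ")
        x = concat([ft, fc], axis=1)
        _, _, h, w = x.shape
        div = 2 ** (self.n_scales - 1)
        ph, pw = (-h) % div, (-w) % div
        if ph:
            x = x.pad_axis_zero(2, 0, ph)
        if pw:
            x = x.pad_axis_zero(3, 0, pw)
        out = None
        for lvl, conv in enumerate(self.convs):
            k = 2 ** lvl
            xi = x if k == 1 else x.avg_pool2d(k)
            yi = conv(xi)
            if k > 1:
                yi = yi.upsample_bilinear(k)
            out = yi if out is None else out + yi
        if ph or pw:
            out = out[:, :, :h, :w]
        return out


class Upsampler(Module):
    """Sub-pixel reconstruction: (conv d->4d, pixel shuffle x2) per stage,
    then a zero-initialised conv to the output channels."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        d = cfg.feature_dim
        self.stages = [Conv2d(d, 4 * d, 3, rng)
                       for _ in range(int(np.log2(cfg.scale)))]
        self.final = Conv2d(d, cfg.in_channels, 3, rng, zero_init=True)

    def __call__(self, x: Tensor) -> Tensor:
        for conv in self.stages:
            x = conv(x).pixel_shuffle(2)
        return self.final(x)


# ----------------------------------------------------------------- network

class DualPathSRNet(Module):
    """Full network; `path` restricts to a single branch for ablations."""

    def __init__(self, cfg: ModelConfig, seed: int = 0, path: str = "dual"):
        if path not in ("dual", "transformer", "cnn"):
            raise ConfigError("path must be dual|transformer|cnn")
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.path = path
        d = cfg.feature_dim
        self.shallow = Conv2d(cfg.in_channels, d, 3, rng, pad_mode="reflect")
        self.rstbs = ([RSTB(cfg, rng) for _ in range(cfg.n_rstb)]
                      if path in ("dual", "transformer") else [])
        self.rcabs = ([RCAB(cfg, rng) for _ in range(cfg.n_rcab)]
                      if path in ("dual", "cnn") else [])
        self.fusion = Fusion(cfg, rng) if path == "dual" else None
        self.single_proj = (None if path == "dual"
                            else Conv2d(d, d, 1, rng))
        self.upsampler = Upsampler(cfg, rng)

    # -- path pieces (exposed for oracle tests) --
    def shallow_extract(self, lr: Tensor) -> Tensor:
        return self.shallow(lr)

    def transformer_path(self, f0: Tensor) -> Tensor:
        ws = self.cfg.window
        _, _, h, w = f0.shape
        ph, pw = (-h) % ws, (-w) % ws
        x = f0
        if ph:
            x = x.pad_axis_zero(2, 0, ph)
        if pw:
            x = x.pad_axis_zero(3, 0, pw)
        for block in self.rstbs:
            x = block(x)
        if ph or pw:
            x = x[:, :, :h, :w]
        return x

    def cnn_path(self, f0: Tensor) -> Tensor:
        x = f0
        for block in self.rcabs:
            x = block(x)
        return x

    def reconstruct(self, ff: Tensor, lr_images: np.ndarray) -> Tensor:
        res = self.upsampler(ff)
        s = self.cfg.scale
        ups = np.stack([
            np.moveaxis(resize_bicubic(np.moveaxis(im, 0, 2),
                                       (im.shape[1] * s, im.shape[2] * s)),
                        2, 0) if im.shape[0] == 3 else
            resize_bicubic(im[0], (im.shape[1] * s, im.shape[2] * s))[None]
            for im in lr_images
        ])
        return res + Tensor(ups)

    def __call__(self, lr: Tensor) -> Tensor:
        """Forward pass NCHW -> NCHW at s x spatial size (un-clipped)."""
        f0 = self.shallow_extract(lr)
        if self.path == "dual":
            ft = self.transformer_path(f0)
            fc = self.cnn_path(f0)
            ff = self.fusion(ft, fc)
        elif self.path == "transformer":
            ff = self.single_proj(self.transformer_path(f0))
        else:
            ff = self.single_proj(self.cnn_path(f0))
        return self.reconstruct(ff, lr.data)

    forward = __call__

    # -- numpy-image convenience --
    def enhance(self, img: np.ndarray) -> np.ndarray:
        """Super-resolve one [0,1] image; output clipped to [0,1]."""
        img = validate_image(img)
        gray = img.ndim == 2
        if gray and self.cfg.in_channels == 3:
            img = np.stack([img] * 3, axis=2)
        x = img[None] if not gray or self.cfg.in_channels == 3 else img[None, None]
        if x.ndim == 4 and x.shape[-1] in (1, 3):
            x = np.moveaxis(x, 3, 1)
        out = self(Tensor(x)).data[0]
        out = np.clip(out, 0.0, 1.0)
        if out.shape[0] == 1:
            return out[0]
        return np.moveaxis(out, 0, 2)


def count_parameters(cfg: ModelConfig, per_component: bool = False):
    """Exact learnable-scalar count for a configuration."""
    net = DualPathSRNet(cfg, seed=0)
    if not per_component:
        return net.n_parameters()
    groups: dict[str, int] = {}
    for name, p in net.named_parameters().items():
        top = name.split(".")[0]
        groups[top] = groups.get(top, 0) + p.data.size
    return groups


# -------------------------------------------------------------- checkpoints

CHECKPOINT_FORMAT = 1


def save_checkpoint(path: str | Path, net: DualPathSRNet,
                    meta: dict | None = None) -> None:
    header = {
        "format": CHECKPOINT_FORMAT,
        "config": net.cfg.to_dict(),
        "path": net.path,
        "meta": meta or {},
    }
    arrays = {f"w::{k}": v for k, v in net.state_dict().items()}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, __header__=json.dumps(header), **arrays)


def load_checkpoint(path: str | Path,
                    expected_cfg: ModelConfig | None = None) -> tuple[DualPathSRNet, dict]:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["__header__"]))
        if header["format"] != CHECKPOINT_FORMAT:
            raise ConfigError(f"unsupported checkpoint format {header['format']}")
        cfg = ModelConfig.from_dict(header["config"])
        if expected_cfg is not None and cfg != expected_cfg:
            raise ConfigError(
                "checkpoint config does not match the requested configuration")
        net = DualPathSRNet(cfg, seed=0, path=header.get("path", "dual"))
        state = {k[3:]: z[k] for k in z.files if k.startswith("w::")}
    net.load_state_dict(state)
    return net, header["meta"]
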