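"""Composite training objective: pixel, perceptual and fractal terms.

``L_total = l1*L_MSE + l2*L_perceptual + l3*L_fractal`` with default
weights (1.0, 0.1, 0.05).

The fractal term compares box-counting dimensions of the two images.
Box counting is not differentiable, so the training path uses a *soft*
surrogate invented for this package: a soft vessel-probability map
(sigmoid of the contrast-normalised inverted green channel at temperature
``tau``), per-box occupancy via max-pooling of probabilities at each
dyadic box size, and the dimension as the closed-form least-squares slope
of log soft-counts against log(1/eps).  As ``tau -> 0`` on binary inputs
the soft counts coincide with the hard box counts, which the test suite
verifies; the hard (non-differentiable) version remains the evaluation
oracle.

The perceptual term is pluggable.  The default offline extractor is a
fixed, seeded random-weight convolutional network — weights are frozen,
deterministic, and require no download; any richer feature extractor
(e.g. a pretrained VGG stage) can be substituted via ``PerceptualSpec``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import ContractError
from .nn import Tensor, concat
from .nn.layers import kaiming
from .vascular import box_sizes_for, fractal_dimension

DEFAULT_TAU = 0.25


@dataclass
class LossWeights:
    mse: float = 1.0
    perceptual: float = 0.1
    fractal: float = 0.05

    def __post_init__(self):
        if min(self.mse, self.perceptual, self.fractal) < 0:
            raise ContractError("loss weights must be >= 0")


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def mse_loss(sr, hr) -> Tensor:
    sr, hr = _lift(sr), _lift(hr)
    if sr.shape != hr.shape:
        raise ContractError(f"mse_loss: shape mismatch {sr.shape} vs {hr.shape}")
    return ((sr - hr) ** 2).mean()


# ------------------------------------------------------------- perceptual

@dataclass
class PerceptualSpec:
    """A deterministic feature extractor phi and its identification tag."""

    extractor: Callable[[Tensor], Tensor]
    tag: str = "random-conv"
    normalize: bool = True


class _RandomConvExtractor:
    """Frozen random-weight 3-stage conv feature extractor (seeded)."""

    def __init__(self, in_channels: int = 3, width: int = 16, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.w1 = Tensor(kaiming(rng, (width, in_channels, 3, 3)))
        self.w2 = Tensor(kaiming(rng, (width, width, 3, 3)))
        self.w3 = Tensor(kaiming(rng, (width, width, 3, 3)))

    def __call__(self, x: Tensor) -> Tensor:
        x = x.conv2d(self.w1, None, padding=1).relu()
        x = x.avg_pool2d(2) if min(x.shape[2:]) >= 8 and \
            x.shape[2] % 2 == 0 and x.shape[3] % 2 == 0 else x
        x = x.conv2d(self.w2, None, padding=1).relu()
        return x.conv2d(self.w3, None, padding=1)


def default_perceptual_spec(in_channels: int = 3, seed: int = 0) -> PerceptualSpec:
    return PerceptualSpec(extractor=_RandomConvExtractor(in_channels, seed=seed))


def perceptual_loss(sr, hr, spec: PerceptualSpec) -> Tensor:
    """Mean squared feature distance, normalised by the feature-map size."""
    sr, hr = _lift(sr), _lift(hr)
    if sr.shape != hr.shape:
        raise ContractError("perceptual_loss: shape mismatch")
    try:
        f_sr = spec.extractor(sr)
        f_hr = spec.extractor(hr)
    except Exception as exc:
        raise ContractError(
            f"perceptual extractor {spec.tag!r} failed: {exc}") from exc
    return ((f_sr - f_hr) ** 2).mean()


# ---------------------------------------------------------------- fractal

def _green(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, H, W) green (or sole) channel."""
    if x.ndim != 4:
        raise ContractError("expected a batched NCHW tensor")
    c = 1 if x.shape[1] == 3 else 0
    return x[:, c, :, :]


def soft_fractal_dimension(x: Tensor, tau: float = DEFAULT_TAU) -> Tensor | None:
    """Differentiable box-counting dimension per batch item, or None when
    the input is flat or offers fewer than 3 dyadic box levels."""
    g = _green(x)
    n, h, w = g.shape
    sizes = box_sizes_for((h, w))
    if len(sizes) < 3:
        return None
    v = 1.0 - g  # vessels are dark; invert so they score high
    mu = v.mean(axis=(1, 2), keepdims=True)
    sd_data = v.data.std(axis=(1, 2))
    if float(sd_data.min()) < 1e-6:
        return None
    var = ((v - mu) ** 2).mean(axis=(1, 2), keepdims=True)
    p = (((v - mu) / (var + 1e-12).sqrt()) * (1.0 / tau)).sigmoid()
    emax = sizes[0]
    ph, pw = (-h) % emax, (-w) % emax
    if ph:
        p = p.pad_axis_zero(1, 0, ph)
    if pw:
        p = p.pad_axis_zero(2, 0, pw)
    hp, wp = h + ph, w + pw
    logs = []
    for e in sizes:
        if e == 1:
            occ_sum = p.sum(axis=(1, 2))
        else:
            blocks = p.reshape(n, hp // e, e, wp // e, e)
            occ_sum = blocks.max(axis=4).max(axis=2).sum(axis=(1, 2))
        logs.append((occ_sum + 1e-8).log().reshape(n, 1))
    ymat = concat(logs, axis=1)                     # (n, k)
    xs = np.log(1.0 / np.asarray(sizes, dtype=float))
    cw = (xs - xs.mean()) / ((xs - xs.mean()) ** 2).sum()
    return (ymat * Tensor(cw[None, :])).sum(axis=1)  # least-squares slope


def fractal_loss(sr, hr, mode: str = "soft", tau: float = DEFAULT_TAU) -> Tensor:
    """|D_f(hr) - D_f(sr)| — soft surrogate for training, hard oracle for
    evaluation.  Hard mode accepts images or binary masks (see
    :func:`vesselsr.vascular.fractal_dimension`)."""
    if mode == "hard":
        sr_a = sr.data if isinstance(sr, Tensor) else np.asarray(sr)
        hr_a = hr.data if isinstance(hr, Tensor) else np.asarray(hr)
        return Tensor(abs(fractal_dimension(np.clip(hr_a, 0, 1))
                          - fractal_dimension(np.clip(sr_a, 0, 1))))
    if mode != "soft":
        raise ContractError("mode must be 'soft' or 'hard'")
    sr, hr = _lift(sr), _lift(hr)
    if sr.shape != hr.shape:
        raise ContractError("fractal_loss: shape mismatch")
    if sr.ndim == 2:
        sr = sr.reshape(1, 1, *sr.shape)
        hr = hr.reshape(1, 1, *hr.shape)
    elif sr.ndim == 3:
        sr = sr.reshape(1, *sr.shape)
        hr = hr.reshape(1, *hr.shape)
    d_sr = soft_fractal_dimension(sr, tau)
    d_hr = soft_fractal_dimension(hr, tau)
    if d_sr is None or d_hr is None:
        warnings.warn("fractal term skipped: flat image or too few box levels",
                      stacklevel=2)
        return Tensor(0.0)
    return (d_sr - d_hr).abs().mean()


# ------------------------------------------------------------------ total

def total_loss(sr, hr, weights: LossWeights | None = None,
               spec: PerceptualSpec | None = None,
               fractal_mode: str = "soft",
               tau: float = DEFAULT_TAU) -> tuple[Tensor, dict[str, float]]:
    """Weighted sum of the three terms; returns (total, component values).

    Components with zero weight are not evaluated (the ablation
    configurations are obtained purely by zeroing weights).
    """
    weights = weights or LossWeights()
    sr_t, hr_t = _lift(sr), _lift(hr)
    comps: dict[str, float] = {"mse": 0.0, "perceptual": 0.0, "fractal": 0.0}
    total = Tensor(0.0)
    c_mse = mse_loss(sr_t, hr_t)
    comps["mse"] = c_mse.item()
    total = total + weights.mse * c_mse
    if weights.perceptual > 0:
        if spec is None:
            in_ch = sr_t.shape[1] if sr_t.ndim == 4 else 3
            spec = default_perceptual_spec(in_ch)
        c_p = perceptual_loss(sr_t, hr_t, spec)
        comps["perceptual"] = c_p.item()
        total = total + weights.perceptual * c_p
    if weights.fractal > 0:
        c_f = fractal_loss(sr_t, hr_t, mode=fractal_mode, tau=tau)
        comps["fractal"] = c_f.item()
        total = total + weights.fractal * c_f
    return total, comps
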