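"""Synthetic fundus-like images with exact ground-truth vessel masks.

The generator emulates the gross photometric structure of a colour fundus
photograph: a dark surround, a circular field of view (FOV) containing a
bright, gently textured background, and a recursively branching tree of
dark vessels entering from the FOV rim and tapering toward the centre.
Vessels absorb light, so they are rendered darker than the background,
with the strongest contrast written to the green channel (channel scales
0.8 / 1.0 / 0.6) as in real fundus photographs.

Two renderings are kept: an anti-aliased stroke for the image, and a hard
rasterisation for the mask, so the mask is unambiguous ground truth for
the vessel-morphology metrics.  Calibration patterns with analytically
known box-counting dimension (line, filled square, Sierpinski triangle,
checkerboard) are provided to validate the fractal estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .errors import ContractError
from . import degrade as _degrade

VESSEL_CHANNEL_SCALE = (0.8, 1.0, 0.6)  # green carries the most contrast
BACKGROUND_CHANNEL_SCALE = (1.0, 0.82, 0.55)  # reddish-orange fundus tint


@dataclass
class VesselTreeParams:
    """Parameters of the procedural vessel tree; identical params (incl.
    seed) yield bit-identical output."""

    seed: int = 0
    image_size: int = 128
    fov_radius_frac: float = 0.96
    n_roots: int = 4
    max_depth: int = 6
    branch_prob: float = 0.7
    angle_jitter: float = 0.35
    initial_width: float = 3.0
    width_decay: float = 0.85
    tortuosity_amp: float = 1.5
    background_level: float = 0.8
    vessel_darkness: float = 0.55
    texture_noise_sd: float = 0.02

    def __post_init__(self):
        if not (0 < self.fov_radius_frac <= 1):
            raise ContractError("fov_radius_frac must be in (0, 1]")
        if not (0 <= self.branch_prob <= 1):
            raise ContractError("branch_prob must be in [0, 1]")
        if not (0 < self.width_decay < 1):
            raise ContractError("width_decay must be in (0, 1)")
        for name in ("background_level", "vessel_darkness", "texture_noise_sd"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ContractError(f"{name} must be in [0, 1]")
        if self.image_size < 16:
            raise ContractError("image_size must be >= 16")
        if self.n_roots < 1 or self.max_depth < 1:
            raise ContractError("n_roots and max_depth must be >= 1")
        if self.initial_width < 1:
            raise ContractError("initial_width must be >= 1 pixel")


@dataclass
class SyntheticFundus:
    image: np.ndarray  # (H, W, 3) float in [0, 1]
    mask: np.ndarray   # (H, W) uint8 in {0, 1}
    params: VesselTreeParams


def _render_stroke(alpha: np.ndarray, mask: np.ndarray, pts: np.ndarray,
                   width: float) -> None:
    """Stamp anti-aliased coverage into `alpha` and hard pixels into `mask`
    along the polyline sample points `pts` (float (n,2) yx)."""
    size = alpha.shape[0]
    half = width / 2.0
    r = int(np.ceil(half + 1.0))
    for y, x in pts:
        yi, xi = int(round(y)), int(round(x))
        y0, y1 = max(yi - r, 0), min(yi + r + 1, size)
        x0, x1 = max(xi - r, 0), min(xi + r + 1, size)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.sqrt((yy - y) ** 2 + (xx - x) ** 2)
        cov = np.clip(half + 0.5 - d, 0.0, 1.0)
        np.maximum(alpha[y0:y1, x0:x1], cov, out=alpha[y0:y1, x0:x1])
        mask[y0:y1, x0:x1] |= d <= max(half, 0.5)


def generate_fundus(params: VesselTreeParams) -> SyntheticFundus:
    """Render one synthetic fundus image plus exact vessel mask."""
    rng = np.random.default_rng(params.seed)
    size = params.image_size
    centre = (size - 1) / 2.0
    fov_r = params.fov_radius_frac * size / 2.0

    alpha = np.zeros((size, size))
    mask = np.zeros((size, size), dtype=bool)

    seg_len = 0.30 * fov_r
    truncated = False

    # stack of (position yx, direction angle, width, depth)
    stack = []
    root_angles = np.linspace(0, 2 * np.pi, params.n_roots, endpoint=False)
    root_angles = root_angles + rng.uniform(0, 2 * np.pi)
    for ang in root_angles:
        pos = np.array([centre + 0.98 * fov_r * np.sin(ang),
                        centre + 0.98 * fov_r * np.cos(ang)])
        heading = ang + np.pi + rng.uniform(-0.3, 0.3)  # point inward
        stack.append((pos, heading, params.initial_width, 0))

    while stack:
        pos, heading, width, depth = stack.pop()
        if depth >= params.max_depth:
            continue
        if width < 0.5:
            truncated = True
            continue
        length = seg_len * (0.85 ** depth)
        direction = np.array([np.sin(heading), np.cos(heading)])
        perp = np.array([direction[1], -direction[0]])
        n_samples = max(int(2 * length), 4)
        ts = np.linspace(0.0, 1.0, n_samples)
        wavelength = 18.0
        phase = rng.uniform(0, 2 * np.pi)
        lateral = params.tortuosity_amp * np.sin(
            2 * np.pi * ts * length / wavelength + phase)
        pts = pos[None, :] + ts[:, None] * length * direction[None, :] \
            + lateral[:, None] * perp[None, :]
        # keep strokes inside the FOV disc
        inside = np.sqrt(((pts - centre) ** 2).sum(axis=1)) <= fov_r - 1.0
        if not inside.any():
            continue
        pts = pts[inside]
        _render_stroke(alpha, mask, pts, width)
        end = pts[-1]
        if rng.uniform() < params.branch_prob:
            split = 0.35 + rng.uniform(0, params.angle_jitter)
            for sgn in (-1.0, 1.0):
                child = heading + sgn * split + rng.uniform(
                    -params.angle_jitter, params.angle_jitter)
                stack.append((end.copy(), child,
                              width * params.width_decay, depth + 1))
        else:
            child = heading + rng.uniform(-params.angle_jitter,
                                          params.angle_jitter)
            stack.append((end.copy(), child,
                          width * params.width_decay, depth + 1))

    if truncated:
        warnings.warn("vessel width fell below 0.5 px before max_depth; "
                      "branch depth truncated", stacklevel=2)

    # background: tinted level plus a smooth texture field plus pixel noise
    texture = ndimage.gaussian_filter(
        rng.normal(0.0, 1.0, (size, size)), sigma=size / 16.0)
    tex_sd = float(texture.std())
    if tex_sd > 0:
        texture = texture / tex_sd * 0.03

    yy, xx = np.mgrid[0:size, 0:size]
    fov = (yy - centre) ** 2 + (xx - centre) ** 2 <= fov_r ** 2
    mask &= fov

    img = np.zeros((size, size, 3))
    for c in range(3):
        bg = params.background_level * BACKGROUND_CHANNEL_SCALE[c] + texture
        dark = params.vessel_darkness * VESSEL_CHANNEL_SCALE[c]
        img[:, :, c] = bg - dark * alpha
    noise = rng.normal(0.0, params.texture_noise_sd, (size, size, 3))
    img = np.clip(img + noise, 0.0, 1.0)
    img[~fov] = 0.0

    return SyntheticFundus(image=img, mask=mask.astype(np.uint8), params=params)


class CalibrationPattern(NamedTuple):
    mask: np.ndarray          # (size, size) uint8 in {0, 1}
    analytic_dimension: float


def generate_calibration(pattern: str, size: int = 512,
                         iterations: int = 7) -> CalibrationPattern:
    """Binary patterns of analytically known box-counting dimension.

    line -> 1.0; filled_square / checkerboard -> 2.0;
    sierpinski (triangle) -> log 3 / log 2 ~ 1.585.
    """
    if iterations < 1:
        raise ContractError("iterations must be >= 1")
    if pattern == "line":
        m = np.zeros((size, size), dtype=np.uint8)
        m[size // 2, :] = 1
        return CalibrationPattern(m, 1.0)
    if pattern == "filled_square":
        return CalibrationPattern(np.ones((size, size), dtype=np.uint8), 2.0)
    if pattern == "checkerboard":
        yy, xx = np.mgrid[0:size, 0:size]
        return CalibrationPattern(((yy + xx) % 2).astype(np.uint8), 2.0)
    if pattern == "sierpinski":
        if size & (size - 1) != 0:
            raise ContractError("sierpinski size must be a power of 2")
        n = 2 ** iterations
        if n > size:
            raise ContractError("2**iterations exceeds size")
        # exact triangle with `iterations` self-similar levels at pixel
        # resolution (Pascal mod 2); its dyadic box counts are exactly
        # 3^(iterations - m), so it calibrates the estimator sharply
        i, j = np.mgrid[0:n, 0:n]
        base = ((i & j) == 0).astype(np.uint8)
        m = np.zeros((size, size), dtype=np.uint8)
        m[:n, :n] = base
        return CalibrationPattern(m, float(np.log(3) / np.log(2)))
    raise ContractError(f"unknown calibration pattern {pattern!r}")


@dataclass
class DatasetItem:
    hr: SyntheticFundus
    lr: np.ndarray
    split: str  # "train" | "val"
    index: int = 0


def make_dataset(n: int, params_template: VesselTreeParams | None = None,
                 scale: int = 2,
                 degradations: list["_degrade.DegradationSpec"] | None = None,
                 seed: int = 0, split_frac: float = 0.8,
                 blur_sigma: float = 1.0) -> list[DatasetItem]:
    """Build a paired LR/HR corpus of synthetic fundus images.

    Each item gets its own child seed; LR inputs are synthesized with
    :func:`vesselsr.degrade.prepare_lr` and then passed through the given
    degradation specs (noise seeds re-derived per item).
    """
    if n < 1:
        raise ContractError("n must be >= 1")
    if params_template is None:
        params_template = VesselTreeParams()
    if degradations is None:
        degradations = []
    if not degradations and blur_sigma == 0.0:
        warnings.warn("empty degradation list: plain bicubic pairing",
                      stacklevel=2)

    items = []
    for i in range(n):
        child = (seed * 100003 + 7919 * i + 1) % (2 ** 31)
        p = replace(params_template, seed=child)
        hr = generate_fundus(p)
        lr = _degrade.prepare_lr(hr.image, scale, blur_sigma=blur_sigma)
        for j, spec in enumerate(degradations):
            lr = _degrade.apply_degradation(lr, spec.with_seed(child + j + 13))
        items.append(DatasetItem(hr=hr, lr=lr, split="train", index=i))

    order = np.random.default_rng(seed + 1).permutation(n)
    n_train = int(round(split_frac * n))
    for rank, idx in enumerate(order):
        items[idx].split = "train" if rank < n_train else "val"
    return items
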