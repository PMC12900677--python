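"""Degradation model for LR synthesis and the six robustness protocols.

LR images are produced as ``I_LR = D(I_HR) + eta``: bicubic downsampling by
the scale factor followed by a Gaussian blur (the literal order used for
the training pairs; a ``blur_first`` switch restores the more common
blur-then-downsample order), with optional additive noise and codec
artefacts layered on top.

The six named robustness protocols are: Gaussian blur sigma=1.2, motion
blur with an 11-pixel kernel at 45 degrees, additive Gaussian noise
sigma=25 (on the 8-bit scale), JPEG at quality 20, 30% radial vignetting,
and a combined protocol applying blur -> noise -> JPEG -> vignette in
acquisition-physics order (optics, sensor, compression, display).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image as PILImage
from scipy import ndimage

from .errors import ContractError
from .imaging import quantize, resize_bicubic, validate_image

KINDS = (
    "bicubic_down", "gaussian_blur", "motion_blur", "gaussian_noise",
    "jpeg", "vignette", "combined",
)


@dataclass
class DegradationSpec:
    """A single degradation operator and its parameters.

    ``sigma`` is in pixels for blurs and in 8-bit intensity units (0-255)
    for noise; ``strength`` is the vignette attenuation at the corner.
    """

    kind: str
    scale: int = 2
    sigma: float = 1.0
    kernel_len: int = 11
    angle: float = 45.0
    quality: int = 20
    strength: float = 0.3
    seed: int = 0
    sub_specs: list = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.kind not in KINDS:
            raise ContractError(f"unknown degradation kind {self.kind!r}")
        if self.sigma < 0:
            raise ContractError("sigma must be >= 0")
        if self.kernel_len < 1 or self.kernel_len % 2 == 0:
            raise ContractError("kernel_len must be odd and >= 1")
        if not (1 <= self.quality <= 100):
            raise ContractError("JPEG quality must be in [1, 100]")
        if not (0.0 <= self.strength <= 1.0):
            raise ContractError("vignette strength must be in [0, 1]")
        if self.kind == "bicubic_down" and self.scale < 1:
            raise ContractError("scale must be >= 1")
        if self.kind == "combined" and not self.sub_specs:
            raise ContractError("combined spec requires sub_specs")
        for sub in self.sub_specs:
            sub.validate()

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind, "scale": self.scale, "sigma": self.sigma,
            "kernel_len": self.kernel_len, "angle": self.angle,
            "quality": self.quality, "strength": self.strength, "seed": self.seed,
        }
        if self.sub_specs:
            d["sub_specs"] = [s.to_dict() for s in self.sub_specs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DegradationSpec":
        d = dict(d)
        subs = [cls.from_dict(s) for s in d.pop("sub_specs", [])]
        return cls(sub_specs=subs, **d)

    def with_seed(self, seed: int) -> "DegradationSpec":
        subs = [s.with_seed(seed + i + 1) for i, s in enumerate(self.sub_specs)]
        return replace(self, seed=seed, sub_specs=subs)


def _blur(img: np.ndarray, sigma: float) -> np.ndarray:
    if sigma == 0:
        return img
    sig = (sigma, sigma) if img.ndim == 2 else (sigma, sigma, 0)
    return np.clip(ndimage.gaussian_filter(img, sig, mode="reflect"), 0.0, 1.0)


def motion_kernel(length: int, angle_deg: float) -> np.ndarray:
    """Normalised 1-pixel-wide line kernel via symmetric midpoint raster."""
    k = np.zeros((length, length))
    c = (length - 1) / 2
    theta = np.deg2rad(angle_deg)
    dx, dy = np.cos(theta), -np.sin(theta)
    m = max(abs(dx), abs(dy))
    # step along the dominant axis so the line spans exactly `length` taps;
    # symmetric about the centre, so 45 degrees yields the full diagonal
    for i in range(length):
        t = i - c
        x = int(round(c + t * dx / m))
        y = int(round(c + t * dy / m))
        k[y, x] = 1.0
    return k / k.sum()


def _convolve(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    if img.ndim == 2:
        out = ndimage.convolve(img, kernel, mode="reflect")
    else:
        out = np.stack(
            [ndimage.convolve(img[:, :, ch], kernel, mode="reflect")
             for ch in range(img.shape[2])], axis=2)
    return np.clip(out, 0.0, 1.0)


def _jpeg(img: np.ndarray, quality: int) -> np.ndarray:
    gray = img.ndim == 2
    u8 = quantize(img, 8)
    pim = PILImage.fromarray(u8, mode="L" if gray else "RGB")
    buf = io.BytesIO()
    pim.save(buf, format="JPEG", quality=int(quality))
    buf.seek(0)
    back = np.asarray(PILImage.open(buf), dtype=np.float64) / 255.0
    return back


def _vignette(img: np.ndarray, strength: float) -> np.ndarray:
    h, w = img.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    r2max = cy ** 2 + cx ** 2
    gain = 1.0 - strength * (r2 / r2max)
    if img.ndim == 3:
        gain = gain[:, :, None]
    return img * gain


def apply_degradation(img: np.ndarray, spec: DegradationSpec) -> np.ndarray:
    """Apply one degradation operator; output stays a valid [0,1] image."""
    img = validate_image(img)
    spec.validate()
    if spec.kind == "bicubic_down":
        h, w = img.shape[:2]
        if h % spec.scale or w % spec.scale:
            raise ContractError("dims not divisible by scale; crop first")
        return resize_bicubic(img, (h // spec.scale, w // spec.scale))
    if spec.kind == "gaussian_blur":
        return _blur(img, spec.sigma)
    if spec.kind == "motion_blur":
        return _convolve(img, motion_kernel(spec.kernel_len, spec.angle))
    if spec.kind == "gaussian_noise":
        if spec.sigma == 0:
            return img
        rng = np.random.default_rng(spec.seed)
        noisy = img + rng.normal(0.0, spec.sigma / 255.0, size=img.shape)
        return np.clip(noisy, 0.0, 1.0)
    if spec.kind == "jpeg":
        return _jpeg(img, spec.quality)
    if spec.kind == "vignette":
        return _vignette(img, spec.strength)
    if spec.kind == "combined":
        out = img
        for sub in spec.sub_specs:
            out = apply_degradation(out, sub)
        return out
    raise ContractError(f"unknown kind {spec.kind!r}")


def prepare_lr(hr: np.ndarray, s: int, blur_sigma: float = 1.0,
               blur_first: bool = False) -> np.ndarray:
    """Synthesize the LR training input: bicubic downsample by ``s`` then
    Gaussian blur of ``blur_sigma`` (set ``blur_first`` to pre-blur instead)."""
    hr = validate_image(hr)
    if s not in (2, 4):
        raise ContractError(f"scale must be 2 or 4, got {s}")
    h, w = hr.shape[:2]
    if h % s or w % s:
        raise ContractError("HR dims not divisible by scale; crop first")
    if blur_first:
        hr = _blur(hr, blur_sigma)
    lr = resize_bicubic(hr, (h // s, w // s))
    if not blur_first:
        lr = _blur(lr, blur_sigma)
    return lr


def protocol_suite() -> list[DegradationSpec]:
    """The six named robustness protocols at their standard severities."""
    blur = DegradationSpec(kind="gaussian_blur", sigma=1.2)
    motion = DegradationSpec(kind="motion_blur", kernel_len=11, angle=45.0)
    noise = DegradationSpec(kind="gaussian_noise", sigma=25.0)
    jpeg = DegradationSpec(kind="jpeg", quality=20)
    vig = DegradationSpec(kind="vignette", strength=0.30)
    combined = DegradationSpec(
        kind="combined",
        sub_specs=[replace(blur), replace(noise), replace(jpeg), replace(vig)],
    )
    return [blur, motion, noise, jpeg, vig, combined]


PROTOCOL_NAMES = ("blur", "motion", "noise", "jpeg", "vignette", "combined")


def protocol_by_name(name: str) -> DegradationSpec:
    suite = dict(zip(PROTOCOL_NAMES, protocol_suite()))
    if name not in suite:
        raise ContractError(
            f"unknown protocol {name!r}; valid names: {', '.join(PROTOCOL_NAMES)}")
    return suite[name]


def noise_severity_grid() -> list[float]:
    """Noise sigma ladder for severity sweeps: clean, low, medium, high, severe."""
    return [0.0, 10.0, 25.0, 35.0, 50.0]
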