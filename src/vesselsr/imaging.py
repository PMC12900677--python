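"""Image container conventions, file I/O and pixel-fidelity metrics.

An image in this package is a plain numpy float64 array with values in
[0, 1], either ``(H, W)`` grayscale or ``(H, W, 3)`` RGB.  Low/high
resolution pairs are related by an integer scale ``s`` on both axes.

Conventions fixed here (documented so alternatives can be added):

* quantisation on write is round-half-away-from-zero;
* PSNR/SSIM are computed on the full RGB signal in [0, 1] (SSIM after a
  fixed luminance conversion with weights 0.299/0.587/0.114);
* identical images report PSNR as ``math.inf``, a deliberate sentinel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from PIL import Image as PILImage
from skimage.metrics import structural_similarity

from .errors import ContractError, IOFailure

LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

PSNR_INF = math.inf


def validate_image(img: np.ndarray, name: str = "image") -> np.ndarray:
    """Check the [0,1] float image contract and return the array as float64."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim not in (2, 3):
        raise ContractError(f"{name}: expected 2-D or 3-D array, got ndim={img.ndim}")
    if img.ndim == 3 and img.shape[2] not in (1, 3):
        raise ContractError(f"{name}: channel count must be 1 or 3, got {img.shape[2]}")
    if img.shape[0] < 8 or img.shape[1] < 8:
        raise ContractError(f"{name}: spatial dims must be >= 8, got {img.shape[:2]}")
    if not np.isfinite(img).all():
        raise ContractError(f"{name}: contains non-finite values")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ContractError(f"{name}: values outside [0, 1]")
    return img


def to_gray(img: np.ndarray) -> np.ndarray:
    """Luminance conversion with fixed Rec.601 weights; grayscale passes through."""
    if img.ndim == 2:
        return img
    if img.shape[2] == 1:
        return img[:, :, 0]
    return img @ LUMA_WEIGHTS


def quantize(img: np.ndarray, bit_depth: int = 8) -> np.ndarray:
    """Round-half-away-from-zero quantisation to the integer grid."""
    if bit_depth not in (8, 16):
        raise ContractError(f"bit_depth must be 8 or 16, got {bit_depth}")
    maxv = 2 ** bit_depth - 1
    q = np.floor(np.abs(img) * maxv + 0.5) * np.sign(img)
    q = np.clip(q, 0, maxv)
    return q.astype(np.uint8 if bit_depth == 8 else np.uint16)


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image into a [0,1] float array (gray or RGB)."""
    path = Path(path)
    if not path.exists():
        raise IOFailure(f"no such image file: {path}")
    try:
        raw = iio.imread(path)
    except Exception as exc:  # decoding failure
        raise IOFailure(f"cannot decode {path}: {exc}") from exc
    if raw.ndim == 3 and raw.shape[2] == 4:
        warnings.warn(f"{path.name}: alpha channel stripped", stacklevel=2)
        raw = raw[:, :, :3]
    if raw.ndim == 3 and raw.shape[2] not in (1, 3):
        raise IOFailure(f"{path}: unsupported channel count {raw.shape[2]}")
    if raw.dtype == np.uint8:
        img = raw.astype(np.float64) / 255.0
    elif raw.dtype == np.uint16:
        img = raw.astype(np.float64) / 65535.0
    else:
        raise IOFailure(f"{path}: unsupported dtype {raw.dtype}")
    if img.ndim == 3 and img.shape[2] == 1:
        img = img[:, :, 0]
    return img


def write_image(img: np.ndarray, path: str | Path, bit_depth: int = 8) -> None:
    """Write a [0,1] image to PNG/TIFF at the given bit depth."""
    img = validate_image(img)
    path = Path(path)
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        iio.imwrite(path, quantize(img, bit_depth))
    except (OSError, PermissionError) as exc:
        raise IOFailure(f"cannot write {path}: {exc}") from exc


def resize_bicubic(img: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Bicubic resampling (Pillow kernel) used for LR synthesis and the
    global residual upsampling path; output clipped back to [0, 1]."""
    h, w = out_hw
    if img.ndim == 2:
        pim = PILImage.fromarray(img.astype(np.float32), mode="F")
        out = np.asarray(pim.resize((w, h), PILImage.BICUBIC), dtype=np.float64)
    else:
        out = np.stack(
            [resize_bicubic(img[:, :, c], out_hw) for c in range(img.shape[2])],
            axis=2,
        )
    return np.clip(out, 0.0, 1.0)


def psnr(a: np.ndarray, b: np.ndarray, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB over all channels jointly."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ContractError(f"psnr: shape mismatch {a.shape} vs {b.shape}")
    if data_range <= 0:
        raise ContractError("psnr: data_range must be positive")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return PSNR_INF
    return 10.0 * math.log10(data_range ** 2 / mse)


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Mean structural similarity with an 11x11 Gaussian window (sigma 1.5).

    RGB inputs are converted to luminance first; the result lies in [-1, 1].
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ContractError(f"ssim: shape mismatch {a.shape} vs {b.shape}")
    ga, gb = to_gray(a), to_gray(b)
    if min(ga.shape) < 11:
        raise ContractError("ssim: image smaller than the 11x11 window")
    return float(
        structural_similarity(
            ga, gb, win_size=11, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, data_range=1.0,
        )
    )


def retention_pct(clean: float, degraded: float) -> float:
    """PSNR retention 100*degraded/clean, the robustness summary statistic."""
    if not (math.isfinite(clean) and math.isfinite(degraded)):
        raise ContractError("retention_pct: inputs must be finite")
    if clean <= 0:
        raise ContractError("retention_pct: clean PSNR must be positive")
    return 100.0 * degraded / clean


@dataclass
class MetricReport:
    """Full fidelity + vascular-morphology report for an image pair."""

    psnr: float
    ssim: float
    delta_df: float | None = None
    vci: float | None = None
    vtp: float | None = None
    retention_pct: float | None = None
    clinical_category: str | None = None

    def __post_init__(self):
        if self.vci is not None and not (0.0 <= self.vci <= 1.0):
            raise ContractError(f"vci out of [0,1]: {self.vci}")
        if self.vtp is not None and not (0.0 <= self.vtp <= 1.0):
            raise ContractError(f"vtp out of [0,1]: {self.vtp}")

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["psnr"] == PSNR_INF:
            d["psnr"] = "inf"
        return d
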