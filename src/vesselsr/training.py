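"""Optimisation loop: cosine-annealed Adam, patch sampling, augmentation,
progressive degradation curriculum, validation and checkpointing.

The learning rate follows ``eta_t = eta_min + (eta_max - eta_min)/2 *
(1 + cos(t*pi/T))`` per epoch.  Training starts on mildly degraded pairs
(bicubic downsampling + Gaussian blur sigma 1.0) and, after a
configurable fraction of the epochs, additionally draws per-sample
degradations from a menu of sub-protocol severities (blur <= 1.2, noise
<= 25, JPEG >= 20) — the two-phase curriculum.

All randomness derives from ``(seed, epoch)`` so runs are bit-reproducible
and training resumed from a checkpoint continues the schedule exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .degrade import DegradationSpec, apply_degradation
from .errors import ContractError
from .imaging import psnr as _psnr, resize_bicubic, ssim as _ssim
from .losses import LossWeights, default_perceptual_spec, total_loss
from .model import DualPathSRNet, ModelConfig, save_checkpoint
from .nn import Adam, Tensor
from .synthetic import DatasetItem
from .vascular import delta_df as _delta_df


@dataclass
class TrainConfig:
    eta_max: float = 2e-4
    eta_min: float = 1e-6
    epochs: int = 300
    steps_per_epoch: int = 50
    batch: int = 16
    patch: int = 64          # LR-side patch size
    betas: tuple = (0.9, 0.999)
    adam_eps: float = 1e-8
    seed: int = 0
    curriculum_switch: float = 0.3
    weights: LossWeights = field(default_factory=LossWeights)
    fractal_tau: float = 0.25
    flips: bool = True
    rotation: bool = True
    jitter: bool = True
    val_delta_df: bool = False
    grad_clip: float = 0.0   # 0 disables clipping

    def __post_init__(self):
        if not (0 <= self.eta_min <= self.eta_max):
            raise ContractError("require 0 <= eta_min <= eta_max")
        if self.epochs < 1 or self.batch < 1 or self.steps_per_epoch < 1:
            raise ContractError("epochs, batch, steps_per_epoch must be >= 1")


def cosine_lr(t: int, cfg: TrainConfig) -> float:
    """Cosine annealing from eta_max (t=0) to eta_min (t=T)."""
    if not (0 <= t <= cfg.epochs):
        raise ContractError(f"epoch {t} outside [0, {cfg.epochs}]")
    return cfg.eta_min + 0.5 * (cfg.eta_max - cfg.eta_min) * (
        1.0 + math.cos(t * math.pi / cfg.epochs))


# ------------------------------------------------------------ augmentation

def augment(lr_patch: np.ndarray, hr_patch: np.ndarray, seed: int,
            flips: bool = True, rotation: bool = True,
            jitter: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Apply the same seeded geometric/photometric transform to both patches."""
    rng = np.random.default_rng(seed)
    lr, hr = lr_patch, hr_patch
    if flips:
        if rng.uniform() < 0.5:
            lr, hr = lr[:, ::-1], hr[:, ::-1]
        if rng.uniform() < 0.5:
            lr, hr = lr[::-1], hr[::-1]
    if rotation:
        k = int(rng.integers(0, 4))
        if k:
            lr = np.rot90(lr, k, axes=(0, 1))
            hr = np.rot90(hr, k, axes=(0, 1))
    if jitter:
        gain = 1.0 + rng.uniform(-0.05, 0.05)
        offs = rng.uniform(-0.05, 0.05)
        lr = np.clip(lr * gain + offs, 0.0, 1.0)
        hr = np.clip(hr * gain + offs, 0.0, 1.0)
    return np.ascontiguousarray(lr), np.ascontiguousarray(hr)


def sample_patches(lr_img: np.ndarray, hr_img: np.ndarray, n: int, patch: int,
                   scale: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """n aligned (LR, HR) crops: LR of size `patch`, HR of size scale*patch
    at scale x the offsets."""
    h, w = lr_img.shape[:2]
    if h < patch or w < patch:
        raise ContractError(f"image {h}x{w} smaller than patch {patch}")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        y = int(rng.integers(0, h - patch + 1))
        x = int(rng.integers(0, w - patch + 1))
        lp = lr_img[y:y + patch, x:x + patch]
        hp = hr_img[scale * y:scale * (y + patch),
                    scale * x:scale * (x + patch)]
        out.append((lp, hp))
    return out


# -------------------------------------------------------------- curriculum

def curriculum_stage(epoch: int, cfg: TrainConfig) -> list[DegradationSpec]:
    """Degradation menu at the given epoch.  Phase 1 (early epochs): the
    base bicubic+blur pairing only.  Phase 2: sub-protocol severities are
    additionally drawn per sample."""
    if epoch >= cfg.epochs:
        raise ContractError("epoch must be < total epochs")
    base = DegradationSpec(kind="bicubic_down", scale=2, sigma=1.0)
    if epoch < cfg.curriculum_switch * cfg.epochs:
        return [base]
    return [
        base,
        DegradationSpec(kind="gaussian_blur", sigma=1.2),
        DegradationSpec(kind="gaussian_noise", sigma=25.0),
        DegradationSpec(kind="jpeg", quality=20),
    ]


# ------------------------------------------------------------- the trainer

@dataclass
class EpochRecord:
    epoch: int
    lr: float
    loss: float
    components: dict
    val_psnr: float
    val_ssim: float
    val_delta_df: float | None = None

    def to_dict(self):
        return asdict(self)


class TrainHistory(list):
    """Per-epoch records; serialises to JSON lines."""

    def write_jsonl(self, path):
        with open(path, "w") as fh:
            for rec in self:
                fh.write(json.dumps(rec.to_dict()) + "\n")


def _to_nchw(patches: list[np.ndarray]) -> np.ndarray:
    arr = np.stack(patches)
    if arr.ndim == 3:
        arr = arr[:, None]
    else:
        arr = np.moveaxis(arr, 3, 1)
    return arr


def evaluate_pairs(net: DualPathSRNet, items: list[DatasetItem],
                   with_delta_df: bool = False) -> dict:
    """Mean validation metrics of a model over LR/HR items."""
    psnrs, ssims, dds = [], [], []
    for it in items:
        sr = net.enhance(it.lr)
        hr = it.hr.image
        psnrs.append(_psnr(hr, sr))
        ssims.append(_ssim(hr, sr))
        if with_delta_df:
            dds.append(_delta_df(hr, sr))
    out = {"psnr": float(np.mean(psnrs)), "ssim": float(np.mean(ssims))}
    out["delta_df"] = float(np.mean(dds)) if dds else None
    return out


def bicubic_baseline(items: list[DatasetItem],
                     scale: int, with_delta_df: bool = False) -> dict:
    """The same metrics for plain bicubic upsampling of the LR inputs."""
    psnrs, ssims, dds = [], [], []
    for it in items:
        h, w = it.lr.shape[:2]
        up = resize_bicubic(it.lr, (h * scale, w * scale))
        psnrs.append(_psnr(it.hr.image, up))
        ssims.append(_ssim(it.hr.image, up))
        if with_delta_df:
            dds.append(_delta_df(it.hr.image, up))
    out = {"psnr": float(np.mean(psnrs)), "ssim": float(np.mean(ssims))}
    out["delta_df"] = float(np.mean(dds)) if dds else None
    return out


def train(model_cfg: ModelConfig, data: list[DatasetItem], cfg: TrainConfig,
          out_dir: str | Path | None = None, path: str = "dual",
          net: DualPathSRNet | None = None, start_epoch: int = 0,
          end_epoch: int | None = None,
          opt_state: dict | None = None) -> tuple[DualPathSRNet, TrainHistory]:
    """Seeded end-to-end training; returns the network and its history.

    Passing ``net``/``start_epoch``/``opt_state`` resumes a checkpointed
    run; because per-epoch randomness derives from (seed, epoch), the
    continuation reproduces the uninterrupted schedule exactly.
    """
    train_items = [it for it in data if it.split == "train"]
    val_items = [it for it in data if it.split == "val"]
    if not train_items or not val_items:
        raise ContractError("need non-empty train and validation splits")

    if net is None:
        net = DualPathSRNet(model_cfg, seed=cfg.seed, path=path)
    params = net.parameters()
    opt = Adam(params, lr=cfg.eta_max, betas=tuple(cfg.betas), eps=cfg.adam_eps)
    if opt_state is not None:
        opt.t = opt_state["t"]
        opt.m = [m.copy() for m in opt_state["m"]]
        opt.v = [v.copy() for v in opt_state["v"]]
    pspec = default_perceptual_spec(model_cfg.in_channels, seed=cfg.seed)
    scale = model_cfg.scale

    history = TrainHistory()
    best_psnr = -np.inf
    out_dir = Path(out_dir) if out_dir is not None else None

    for epoch in range(start_epoch, cfg.epochs if end_epoch is None else end_epoch):
        lr_now = cosine_lr(epoch, cfg)
        opt.lr = lr_now
        rng = np.random.default_rng([cfg.seed, epoch])
        menu = curriculum_stage(epoch, cfg)
        epoch_losses = []
        comp_sums = {"mse": 0.0, "perceptual": 0.0, "fractal": 0.0}
        for step in range(cfg.steps_per_epoch):
            lr_batch, hr_batch = [], []
            for b in range(cfg.batch):
                it = train_items[int(rng.integers(len(train_items)))]
                pseed = int(rng.integers(2 ** 31))
                (lp, hp), = sample_patches(it.lr, it.hr.image, 1,
                                           cfg.patch, scale, pseed)
                if len(menu) > 1 and rng.uniform() < 0.5:
                    extra = menu[1 + int(rng.integers(len(menu) - 1))]
                    lp = apply_degradation(lp, extra.with_seed(pseed + 1))
                lp, hp = augment(lp, hp, pseed + 2, cfg.flips,
                                 cfg.rotation, cfg.jitter)
                lr_batch.append(lp)
                hr_batch.append(hp)
            x = Tensor(_to_nchw(lr_batch))
            y = Tensor(_to_nchw(hr_batch))
            sr = net(x)
            loss, comps = total_loss(sr, y, cfg.weights, pspec,
                                     fractal_mode="soft", tau=cfg.fractal_tau)
            if not math.isfinite(loss.item()):
                bad = [k for k, v in comps.items() if not math.isfinite(v)]
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} step {step}; "
                    f"offending component(s): {bad or ['total']}")
            opt.zero_grad()
            loss.backward()
            if cfg.grad_clip > 0:
                total_sq = sum(float((p.grad ** 2).sum())
                               for p in params if p.grad is not None)
                norm = math.sqrt(total_sq)
                if norm > cfg.grad_clip:
                    for p in params:
                        if p.grad is not None:
                            p.grad *= cfg.grad_clip / norm
            opt.step()
            epoch_losses.append(loss.item())
            for k in comp_sums:
                comp_sums[k] += comps[k]

        val = evaluate_pairs(net, val_items, with_delta_df=cfg.val_delta_df)
        rec = EpochRecord(
            epoch=epoch, lr=lr_now, loss=float(np.mean(epoch_losses)),
            components={k: v / cfg.steps_per_epoch for k, v in comp_sums.items()},
            val_psnr=val["psnr"], val_ssim=val["ssim"],
            val_delta_df=val["delta_df"],
        )
        history.append(rec)

        if out_dir is not None:
            meta = {"epoch": epoch, "seed": cfg.seed,
                    "opt": {"t": opt.t}, "val_psnr": val["psnr"]}
            _save_with_opt(out_dir / "last.npz", net, opt, meta)
            if val["psnr"] > best_psnr:
                best_psnr = val["psnr"]
                _save_with_opt(out_dir / "best.npz", net, opt, meta)
            history.write_jsonl(out_dir / "history.jsonl")

    return net, history


def _save_with_opt(path: Path, net: DualPathSRNet, opt: Adam, meta: dict):
    save_checkpoint(path, net, meta)
    with np.load(path, allow_pickle=False) as z:
        arrays = {k: z[k] for k in z.files}
    for i, (m, v) in enumerate(zip(opt.m, opt.v)):
        arrays[f"opt_m::{i}"] = m
        arrays[f"opt_v::{i}"] = v
    np.savez(path, **arrays)


def load_opt_state(path: str | Path) -> dict:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["__header__"]))
        ms = sorted((k for k in z.files if k.startswith("opt_m::")),
                    key=lambda s: int(s.split("::")[1]))
        vs = sorted((k for k in z.files if k.startswith("opt_v::")),
                    key=lambda s: int(s.split("::")[1]))
        return {"t": header["meta"]["opt"]["t"],
                "m": [z[k] for k in ms], "v": [z[k] for k in vs],
                "epoch": header["meta"]["epoch"]}
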