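# vesselsr

Structure-preserving super-resolution for retinal fundus images.

Low-resolution fundus photographs — from telemedicine compression, legacy
cameras or bandwidth-limited screening programmes — obscure the fine
vasculature that diagnosis of diabetic retinopathy depends on. Generic
super-resolution recovers pixels but not necessarily *morphology*: a
reconstruction can score well on PSNR while subtly straightening,
thinning or disconnecting vessels. `vesselsr` is built for researchers
in retinal image analysis who need both halves of that problem:

* a **dual-path super-resolution network** — parallel
  shifted-window-attention (Swin-style) and residual channel-attention
  (CNN) branches over shared shallow features, multi-scale fusion,
  sub-pixel reconstruction, and a global bicubic residual — trained with
  the composite objective

  `L = λ₁·L_MSE + λ₂·L_perceptual + λ₃·L_fractal`,  λ = (1.0, 0.1, 0.05),

  where `L_fractal = |D_f(I_HR) − D_f(I_SR)|` penalises loss of vascular
  complexity through a differentiable soft box-counting surrogate;
* a **vascular morphology evaluation stack**: box-counting fractal
  dimension `D_f` (slope of log N(ε) vs log 1/ε over dyadic box sizes),
  the preservation metric ΔD_f with clinical interpretation bins
  (<0.01 excellent / <0.05 acceptable / <0.10 moderate / ≥0.10
  substantial), vessel connectivity (VCI) and tortuosity-preservation
  (VTP) indices, vessel extraction, PSNR/SSIM and PSNR-retention;
* a **degradation simulator** (bicubic+blur LR synthesis plus six named
  robustness protocols: blur σ=1.2, 11-px motion blur at 45°, noise
  σ=25, JPEG q=20, 30% vignetting, and their combination) and a
  **synthetic fundus generator** producing branching vessel trees with
  exact ground-truth masks, so everything is testable offline with no
  dataset downloads.

The network and its training loop run on a small numpy autograd engine
included in the package (`vesselsr.nn`) — CPU-only, float64,
gradient-checked, and deterministic per seed.

## Worked example

```python
import vesselsr as vsr
import vesselsr.training as training

# 1. synthetic fundus corpus with exact vessel masks (8 images, 2x pairs)
data = vsr.make_dataset(8, vsr.VesselTreeParams(image_size=96), scale=2, seed=0)

# 2. fit the tiny dual-path network for ~800 steps on CPU
sr = vsr.SuperResolver(epochs=8, steps_per_epoch=100, seed=0).fit(data)

# 3. compare against plain bicubic upsampling on the validation split
val = [it for it in data if it.split == "val"]
model = sr.evaluate(val, with_delta_df=True)
base = training.bicubic_baseline(val, scale=2, with_delta_df=True)
print(f"model   PSNR {model['psnr']:.2f} dB   dDf {model['delta_df']:.4f}")
print(f"bicubic PSNR {base['psnr']:.2f} dB   dDf {base['delta_df']:.4f}")
print(f"gain {model['psnr']-base['psnr']:.2f} dB, "
      f"dDf improvement {vsr.improvement_pct(model['delta_df'], base['delta_df']):.1f}%, "
      f"category: {vsr.classify_delta_df(model['delta_df'])}")
```

Output (≈1 CPU-minute):

```
model   PSNR 20.59 dB   dDf 0.0510
bicubic PSNR 18.51 dB   dDf 0.1041
gain 2.08 dB, dDf improvement 51.0%, category: moderate
```

Reading it: after 800 optimisation steps the tiny model reconstructs the
validation images 2.08 dB closer to ground truth than bicubic
interpolation, and its vessel networks deviate from the true fractal
dimension by 0.051 instead of 0.104 — i.e. the enhanced images are just
inside the "moderate deviation" clinical band while bicubic output is in
the "substantial distortion" band. `SuperResolver` follows the
scikit-learn estimator protocol (`get_params`/`set_params`/`clone`,
`fit`/`predict`/`score`), so loss-weight ablations compose with sklearn
model selection.

The same workflows are available from a shell:

```bash
vesselsr generate --n 8 --seed 0 --out data/
vesselsr train --config configs/tiny.yaml --out run/
vesselsr enhance data/ --checkpoint run/best.npz --scale 2 --out sr/
vesselsr degrade data/ --spec suite --out degraded/
vesselsr evaluate data/ sr/ --out report.json
```

Every command writes a `manifest.json` (resolved config, seeds, package
version) from which the run can be reproduced exactly.

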