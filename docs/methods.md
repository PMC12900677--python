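# Methods

## Problem and model

Low-resolution retinal fundus photographs obscure the fine vasculature
that screening for diabetic retinopathy depends on. The package treats
single-image super-resolution as learning an approximate inverse of the
degradation `I_LR = D(I_HR) + eta`, where `D` is bicubic downsampling by
an integer factor `s in {2, 4}` composed with Gaussian blur, and `eta` is
additive noise. Beyond pixel fidelity, the reconstruction must preserve
*vascular morphology*: the box-counting fractal dimension `D_f` of the
vessel network is a clinical biomarker (healthy eyes cluster near
`D_f ~ 1.45`, and shifts of ~0.01 are diagnostically meaningful), so the
quantity optimised and reported throughout is the absolute dimension
difference `dDf = |D_f(I_HR) - D_f(I_SR)|` alongside PSNR/SSIM.

The network is dual-path. A single 3x3 convolution lifts the LR image to
`d` feature channels. A transformer path stacks residual blocks of
shifted-window multi-head self-attention layers (window `w`, alternating
shifts of `w/2` with masked cross-window attention, learned relative
position bias, pre-norm MLPs of ratio 2, trailing 3x3 conv, block
residual) to model global context. A CNN path stacks residual
channel-attention blocks (conv-ReLU-conv with a squeeze/excite gate
`sigma(W2 ReLU(W1 GAP(F)))`, reduction 16) to preserve local edges. The
two feature maps are fused by channel concatenation, a pooled pyramid at
scales {1, 1/2, 1/4}, per-level 1x1 convolutions back to `d` channels,
bilinear re-expansion and summation. Reconstruction uses sub-pixel
convolution (one conv to `4d` channels + depth-to-space x2 per octave of
`s`), and the bicubically upsampled input is added back as a global
residual. The final convolution is zero-initialised, so an untrained
network reproduces the bicubic baseline exactly — a property the tests
assert bitwise and which makes early training stable.

The reference configuration is `d=180`, 6 transformer blocks of 6 layers,
8 CNN blocks, window 8, 8 heads. All experiments in this repository use
the `tiny` preset (`d=16`, 1 transformer block of 2 layers, 2 CNN blocks,
window 4, 2 heads, ~28k parameters), which trains in minutes on one CPU.

## Training objective

`L_total = l1 L_MSE + l2 L_perc + l3 L_fractal`, defaults
`(l1, l2, l3) = (1.0, 0.1, 0.05)`.

* `L_MSE` — mean squared error over all pixels and channels.
* `L_perc` — mean squared distance between deep features of the two
  images, normalised by the feature-map size. The extractor is pluggable;
  the default is a fixed, seeded random-weight 3-stage convolutional
  extractor, so the package trains and tests fully offline. Random
  convolutional features are a standing-in perceptual metric, not a
  trained one; a pretrained backbone stage can be dropped in via
  `PerceptualSpec`.
* `L_fractal = |D_f(hr) - D_f(sr)|` — box counting is a discrete count
  and therefore non-differentiable, so the training path uses a **soft
  surrogate** (this module's central construction): the green channel is
  inverted (vessels absorb light and are dark), contrast-normalised to
  zero mean / unit variance, and squashed by a sigmoid at temperature
  `tau` (default 0.25) into a vessel-probability map; per box size
  `eps in {1, 2, 4, ..., min(H,W)/4}` the soft occupancy of each box is
  the max-pooled probability and the soft count `N(eps)` their sum; the
  soft dimension is the closed-form least-squares slope of `log N(eps)`
  against `log(1/eps)`. On binary inputs the soft counts converge to the
  hard counts as `tau -> 0` (verified against the hard counter to within
  0.02 in the tests). The hard, non-differentiable version remains the
  evaluation oracle; validation `dDf` is always computed in hard mode.
  Patches offering fewer than 3 dyadic box levels skip the term for that
  step with a warning.

The loss is computed on the un-clipped network output (clipping to [0,1]
happens only at export) so gradients stay alive at saturation.

Optimisation: Adam `(0.9, 0.999, eps 1e-8)`; learning rate follows cosine
annealing `eta_t = eta_min + (eta_max - eta_min)(1 + cos(t pi / T))/2`
per epoch, reference `eta_max = 2e-4` over `T = 300` epochs with batch 16
and 64-px LR patches (the 64-px patch is interpreted as the LR side, so
HR patches are `64 s`; this is configurable). `eta_min` defaults to
`1e-6`. Augmentation applies identical seeded flips, 90-degree rotations
and ±5% brightness/contrast jitter to both patches. The degradation
curriculum has two phases: before `0.3 T` LR synthesis is bicubic + blur
sigma 1.0 only; afterwards each sample additionally draws, with
probability 1/2, one of {blur sigma<=1.2, noise sigma<=25, JPEG q>=20} at
sub-protocol severity. The switch point, menu and phase count are not
canonical — all three are config-exposed choices. Per-epoch randomness
derives from `(seed, epoch)`, so runs are bit-reproducible and a resumed
checkpoint continues the schedule exactly (Adam moments are stored in the
checkpoint).

## Vascular metrics

* **Extraction**: green-channel inversion, local-mean adaptive threshold
  (window 25 px, offset 0.02), opening with a 3x3 cross, removal of
  components under 20 px, and exclusion of the circular field-of-view rim
  (estimated from near-zero pixels, eroded by 4). The window/offset/area
  values are calibrated so extraction reaches Dice >= 0.7 against the
  synthetic generator's exact masks; all three are parameters.
* **Box counting**: box sides halve per level (powers of two) from
  `min(H, W)/4` down to 1 px; the grid is zero-padded to a multiple of
  each `eps`; `D_f` is the least-squares slope with `R^2` reported, and a
  result outside [0, 2.2] is flagged. At `eps = 1` the count equals the
  pixel count, and all counts are checked against a brute-force
  nested-loop counter in the tests. An empty mask is an error, never a
  silent zero — zeros would poison `dDf` averages.
* **VCI / VTP**: the connectivity and tortuosity indices are *defined by
  this package* (the literature names them without formulas).
  `VCI = 1 - |c_sr - c_hr| / max(c_sr, c_hr)` from skeleton
  connected-component counts;
  `VTP = max(0, 1 - |mean tau_sr - mean tau_hr| / mean tau_hr)` from
  arc/chord tortuosity of skeleton branches (paths between
  endpoints/junctions) of arc length >= 10 px. Both are symmetric-built,
  bounded in [0, 1], and exactly 1 on identical masks.
* **Interpretation bins** for `dDf`, left-closed: `[0, 0.01)` excellent,
  `[0.01, 0.05)` acceptable, `[0.05, 0.10)` moderate, `[0.10, inf)`
  substantial.

## Degradation protocols

Six named robustness protocols: Gaussian blur sigma 1.2 px; motion blur
with an 11-tap midpoint-rasterised line kernel at 45 degrees (unit sum);
additive Gaussian noise sigma 25 on the 8-bit scale (sigma/255 in [0,1],
seeded, clipped); JPEG at quality 20 through the standard baseline codec;
radial vignetting `1 - 0.3 (r/r_max)^2` with `r_max` the half-diagonal
(30% attenuation at the corner); and a combined protocol applying
blur -> noise -> JPEG -> vignette in acquisition-physics order (optics,
sensor, compression, display) — the membership and order of the combined
protocol are package choices, configurable. The noise severity ladder for
sweeps is sigma in {0, 10, 25, 35, 50}; the "low" rung is fixed at 10.
LR training pairs are synthesized by bicubic downsampling *then* blur
(a `blur_first` switch restores the more common pre-blur order; the
choice is recorded in run manifests). PSNR retention is
`100 * degraded/clean`.

## Synthetic data

The generator emulates what the metrics need from a fundus photograph: a
circular field of view on a black surround; a bright, reddish, gently
textured background (smooth Gaussian-filtered field + per-pixel noise of
sd 0.02); and a recursively branching vessel tree entering from the FOV
rim, with per-level width decay 0.85 from 3 px, branch probability 0.7
over 6 levels, sinusoidal centreline wobble (amplitude 1.5 px), and
vessel darkness 0.55 scaled per channel (0.8, 1.0, 0.6) so the green
channel carries the most contrast, as in real photographs. The image is
rendered anti-aliased; the mask is a hard rasterisation of the same
strokes, making it unambiguous ground truth. Defaults were chosen once
for visual plausibility and a mask dimension near the retinal range
(~1.4 at 128 px); generated tortuosity and dimension respond
monotonically to their parameters (tested over seeds).

What it does **not** emulate: optic disc, macula, pathology
(microaneurysms, exudates), optics PSF, inter-image illumination fields,
or camera noise statistics. Passing tests therefore demonstrate that the
algorithms behave correctly on vascular geometry with known ground truth —
not clinical performance on real fundus images.

Calibration patterns with analytic dimension validate the estimator: a
1-px line (1.0), the filled grid (2.0), a checkerboard (2.0), and the
exact Sierpinski triangle with `k` self-similar levels at pixel
resolution (Pascal-mod-2 construction, dimension `log 3 / log 2`), whose
dyadic box counts are exactly `3^(k-m)`.

## Problem sizes and numerical choices

Experiments here run at desk scale by design: datasets of 8 synthetic
96-px images (80/20 split), the tiny preset, 16-px LR patches, batch 4,
~2000 optimisation steps (~2-3 CPU-minutes), learning rate 2e-3 scaled up
from the reference 2e-4 to suit the shorter schedule and smaller model.
Directional experiments (fractal-loss ablation over 5 seeds; dual-path
vs single-path over 3 seeds at 800 steps) reproduce the sign of the
reference effects, not their magnitudes; absolute published benchmark
values require full-scale GPU training on real datasets and are out of
scope. Other fixed choices: float64 arithmetic end to end;
round-half-away-from-zero quantisation on image export; PSNR of
identical images reported as an infinite sentinel; SSIM with an 11x11
Gaussian window (sigma 1.5) on Rec.601 luminance; PSNR/SSIM computed on
RGB in [0, 1] (the luminance-only convention can be added); softmax
computed with max subtraction; `1e-8` floors inside logs of soft counts;
degenerate flat images return a zero soft-fractal term with a warning.

## Known limitations

* The numpy training stack is single-threaded and desk-scale; the full
  `d=180` configuration is constructible and counted, but not trainable
  here in reasonable time.
* VCI/VTP are package-defined formulas; numbers are not comparable to
  other implementations of identically named metrics.
* The skeleton branch decomposition treats every junction pixel as a
  node; very dense junction clusters can split branches conservatively.
* JPEG round-trips quantise to 8 bits internally, so gradients never
  flow through the codec (it is used only for data synthesis).
* The random-weight perceptual extractor measures feature-space
  distortion but carries no semantic prior.
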