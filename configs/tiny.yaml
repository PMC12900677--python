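# Desk-scale training configuration: tiny dual-path network, 2x scale,
# synthetic fundus corpus. Trains in a few CPU-minutes.
data:
  n: 8
  image_size: 96
  seed: 0
model:
  preset: tiny
  scale: 2
train:
  epochs: 8
  steps_per_epoch: 100
  batch: 4
  patch: 16
  eta_max: 0.002
  seed: 0
  weights: {mse: 1.0, perceptual: 0.1, fractal: 0.05}
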