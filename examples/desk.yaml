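# Desk-scale end-to-end run: small synthetic dataset, reduced-width network.
seed: 5
generator:
  image_size: 256
  counts: {rot: 40, spot: 40, scar: 40, crack: 40, normal: 40}
dataset:
  augment_test: false
model:
  width_multiplier: 0.25
loss:
  name: wsoftmax
  gamma: 1.0
swa:
  enabled: true
  start_epoch: 6
  alpha1: 0.02
  alpha2: 0.01
  n_cycles: 10
training:
  epochs: 10
  base_lr: 0.02
  batch_size: 32
  train_resolution: 50
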