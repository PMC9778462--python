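# Full-scale training protocol: 256x256 inputs, batch 32, two discriminator
# updates per generator update, 300 epochs, Adam. Expect GPU-class runtimes;
# the desk profile is the practical CPU setting.
seed: 0
generator:
  base_channels: 32
discriminator:
  channel_schedule: [16, 32, 64, 64]
training:
  batch_size: 32
  disc_steps_per_gen: 2
  epochs: 300
  learning_rate: 1.0e-4
phantoms:
  size: [256, 256]
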