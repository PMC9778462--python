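# CPU-sized profile: small widths, small phantoms, short schedule.
seed: 0
generator:
  base_channels: 8
discriminator:
  channel_schedule: [8, 16, 32]
training:
  batch_size: 4
  disc_steps_per_gen: 2
  epochs: 5
phantoms:
  size: [64, 64]
  blob_sigma: 5.0
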