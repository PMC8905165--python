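# CENP-E_FL-mNeon: full-length motor, single mNeonGreen per monomer
# (2 fluorophores per dimer). Velocities are a two-population mixture:
# a slow-moving majority and a fast population comparable to the truncations.
# The slow/fast weights (0.75/0.25) are a modelling choice; only the
# qualitative majority is reported experimentally.
name: cenpefl
n_events: 61
motor:
  landing_rate_total: 0.147
  processive_fraction: 0.061
  velocity_components:
    - [0.75, 46.4, 12.716]       # sd = s.e.m. 1.88 x sqrt(0.75*61)
    - [0.25, 157.98, 42.06]      # sd = s.e.m. 10.77 x sqrt(0.25*61)
  run_length_mean: 1258.9
  residency_mean: 37.1
  pause_entry_rate: 0.0
  pause_exit_rate: 0.0
  static_dwell_mean: 1.0
  detach_mode: per_distance
  n_fluorophores: 2
  bleach_rate: 0.3
optics:
  pixel_size: 160.0
  frame_interval: 0.12
  exposure: 0.1
  psf_sigma: 120.0
  photons_per_fluorophore_per_frame: 200.0
  background_mean: 100.0
  read_noise_sd: 2.0
  duration: 120.0
  image_shape: [128, 128]
field:
  n_mts: 98
  length_mean: 10.0
  length_sd: 2.0
  duration_min: 10.0
gliding:
  velocity_mean: 115.7   # nm/s
  velocity_sd: 25.0      # chosen spread; only the mean is reported
  n: 93
seed: 0
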