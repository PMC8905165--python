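# CENP-E_483-2mNeon: minimal motor + first coiled-coil, weak dimer.
# Landing rate and processive fraction were not measured for this construct;
# the values below are plausible placeholders for simulation only.
name: cenpe483
n_events: 346
motor:
  landing_rate_total: 0.3        # placeholder (not measured)
  processive_fraction: 0.1       # placeholder ("small fraction")
  velocity_components:
    - [1.0, 144.2, 143.2]        # sd = s.e.m. 7.7 x sqrt(346)
  run_length_mean: 407.3
  residency_mean: 5.41
  pause_entry_rate: 0.0
  pause_exit_rate: 0.0
  static_dwell_mean: 1.0
  detach_mode: per_distance
  n_fluorophores: 4
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
  n_mts: 100
  length_mean: 10.0
  length_sd: 2.0
  duration_min: 10.0
seed: 0
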