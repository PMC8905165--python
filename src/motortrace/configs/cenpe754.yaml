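# CENP-E_754-2mNeon: truncated construct with five native stalk coiled-coils,
# dimer carrying 2x tandem mNeonGreen per monomer (4 fluorophores).
name: cenpe754
n_events: 289          # single-molecule events behind the fitted values
motor:
  landing_rate_total: 0.392      # events/(um*min)
  processive_fraction: 0.513
  velocity_components:           # [weight, mean nm/s, sd nm/s]
    - [1.0, 180.0, 40.8]         # sd = s.e.m. 2.4 x sqrt(289)
  run_length_mean: 703.3         # nm
  residency_mean: 5.3            # s
  pause_entry_rate: 0.0
  pause_exit_rate: 0.0
  static_dwell_mean: 1.0
  detach_mode: per_distance
  n_fluorophores: 4
  bleach_rate: 0.3               # per s per fluorophore
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
  length_mean: 10.0    # um
  length_sd: 2.0
  duration_min: 10.0   # landing-rate observation window
seed: 0
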