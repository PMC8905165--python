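# K560-2mNeon: constitutively active kinesin-1 truncation (KIF5B 1-560) with
# 2x tandem mNeonGreen per monomer (4 fluorophores per dimer), used as the
# intensity/photobleaching reference. Motility parameters follow canonical
# kinesin-1 literature scales; only initial intensities are compared.
name: k560
n_events: 117
motor:
  landing_rate_total: 0.5        # placeholder
  processive_fraction: 0.9       # placeholder
  velocity_components:
    - [1.0, 600.0, 120.0]
  run_length_mean: 1000.0
  residency_mean: 1.67
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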