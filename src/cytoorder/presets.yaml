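# Synthetic-network presets. Each block holds FiberSpec fields; the
# `paired-colocalization` preset additionally carries the pairing options
# consumed by generate_paired.
s2:
  n_fibers: 100
  length_px: 200.0
  width_px: 5.0
  orientations_deg: [[34.0, 1.0]]
  angle_jitter_sd_deg: 0.0
  image_size: [600, 600]
  intensity: 100.0
  psf_sigma_px: 1.5
  photon_scale: 1.0
  read_noise_sd: 5.0
  background_level: 10.0

bimodal-s1:
  n_fibers: 120
  length_px: 120.0
  width_px: 5.0
  orientations_deg: [[30.0, 0.5], [120.0, 0.5]]
  angle_jitter_sd_deg: 0.0
  image_size: [600, 600]

trimodal-s1:
  n_fibers: 150
  length_px: 120.0
  width_px: 5.0
  orientations_deg: [[0.0, 0.3334], [60.0, 0.3333], [120.0, 0.3333]]
  angle_jitter_sd_deg: 0.0
  image_size: [600, 600]

paired-colocalization:
  n_fibers: 40
  length_px: 60.0
  width_px: 3.0
  orientations_deg: [[0.0, 1.0]]
  angle_jitter_sd_deg: 60.0
  image_size: [192, 192]
  shared_fraction: 0.5
  displacement_sd_px: 1.0
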