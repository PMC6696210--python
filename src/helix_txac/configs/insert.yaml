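# Water cylinder with a central Teflon rod and five cylindrical air
# cavities of graded diameter, for contrast/resolution scoring.
# The ring/sinogram settings are finer than the plain desk preset: cavity
# recovery probes system resolution, so the crystal pitch (2.5 mm), the
# radial bins (1.5 mm) and the unapodized-cutoff Hann filter are chosen to
# emulate a clinical ring's intrinsic resolution; exposures are raised to
# keep per-bin transmission counts high enough for an unbiased log-ratio.
seed: 2
phantom:
  kind: insert
  diameter_mm: 130.0
  height_mm: 140.0
  cavity_diameters_mm: [5.0, 8.0, 9.5, 12.0, 16.0]
  cavity_ring_radius_mm: 36.0
  cavity_height_mm: 120.0
  teflon_diameter_mm: 25.0
  teflon_height_mm: 120.0
trajectory:
  helix_radius: 100.0
  z_start: -48.0
  z_end: 48.0
  pitch: 24.0
  speed: 300.0
ring:
  preset: desk
  crystals_per_ring: 384
sinogram:
  n_radial: 135
  radial_width_mm: 1.5
  n_angles: 112
recon:
  n_pixels: 134
  pixel_size_mm: 1.5
  window: hann
  cutoff: 1.0
blank:
  activity_bq: 333333.0
  duration_s: 120.0
transmission:
  activity_bq: 333333.0
  duration_s: 60.0
emission:
  enabled: false
separation:
  source: track
analysis:
  roi_erosion_voxels: 2
  axial_trim_planes: 2
  contrast_threshold: 0.5
output_dir: runs/insert
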