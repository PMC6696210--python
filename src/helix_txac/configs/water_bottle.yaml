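# Homogeneous 1 L water bottle: the headline attenuation-map validation.
# Desk-scale exposures (activity x duration = simulated decays): 1e7
# transmission, 3e7 blank; the blank is longer, as in routine practice,
# and is normalized to the transmission exposure before the log-ratio.
seed: 1
phantom:
  kind: water_bottle
trajectory:
  helix_radius: 100.0
  z_start: -48.0
  z_end: 48.0
  pitch: 24.0
  speed: 300.0
ring:
  preset: desk
blank:
  activity_bq: 166667.0
  duration_s: 180.0
transmission:
  activity_bq: 166667.0
  duration_s: 60.0
emission:
  enabled: false
separation:
  source: track
analysis:
  roi_erosion_voxels: 2
  axial_trim_planes: 2
output_dir: runs/water_bottle
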