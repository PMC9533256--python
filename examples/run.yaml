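# Clinical-scale validation run: standard probe at 15 degC, full region of
# interest, fields at the times compared against MR thermometry.
probe:
  surface_temperature: 15.0
  tip_length: 25.0
domain:
  height: 200.0           # mm; radius defaults to the equal-volume cylinder
solver:
  dt_max: 1.0             # fixed 1 s stepping for short validation runs
times: [0.0, 39.0, 78.0, 136.0, 234.0, 312.0]
mrt:
  noise_sd: 0.5           # degC, per-voxel thermometry noise
seed: 1
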