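{
  "seed": 7,
  "stages": ["simulate", "slabs", "detect", "analyze", "report"],
  "volume": {"n_ascans_x": 128, "n_bscans_y": 32, "n_depth_z": 256, "speckle_shape": 20.0},
  "phantom": {"n_foci": 6},
  "cohort": {"n_eyes": 200},
  "detection": {},
  "log_level": "INFO"
}
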