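# Analysis configuration for movies produced by examples/sim.yaml.
fish: fish0
calibration:
  pixel_size: 1.0        # um per pixel (mandatory user input)
  frame_interval: 2.0    # minutes per frame
  channel_roles:
    0: neutrophil
    1: macrophage
    2: lesion
segmentation:
  neutrophil_threshold: 105.0   # fixed intensity; use "otsu" for automatic
  smoothing_sigma: 1.0
  neutrophil_min_area_um2: 30.0
  neutrophil_max_area_um2: 800.0
  macrophage_min_area_um2: 10.0
  macrophage_max_area_um2: 300.0
  prob_threshold: 0.5
  classifier_seed: 0
tracking:
  max_link_distance_um: 30.0
  max_gap_frames: 2
interactions:
  thresholds_um:
    neutrophil: 20.0    # cytoplasmic margin, strict
    macrophage: 50.0    # nuclear margin, strict
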