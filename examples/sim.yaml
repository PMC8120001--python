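# Simulated movie: 60 frames at 2 min/frame (2 h), 512x512 px at 1 um/px,
# five neutrophils and five macrophages around one static lesion.
simulation:
  seed: 1
  n_frames: 60
  frame_interval_min: 2.0
  pixel_size_um: 1.0
  height: 512
  width: 512
  n_neutrophils: 5
  n_macrophages: 5
  speed_um_min: 6.0
  persistence: 0.5
  bias: 0.0
  noise_sd: 20.0
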