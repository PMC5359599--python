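# Image-mode demo: renders two replicate 96-well plates of two-channel
# synthetic microscopy images and quantifies them end to end.
mode: image
seed: 13
output_dir: demo_image_out
screen:
  n_compounds: 76
  controls_per_role: 8
  n_replicates: 2
  n_rows: 8
  n_cols: 12
simulation:
  cells_per_well: 300
  image_size: [512, 512]
  planted_hits: [C0011, C0042, C0063]
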