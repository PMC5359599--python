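# Summary-mode demo: a two-replicate 384-well screen with three planted
# responder compounds and one cytotoxic responder that must be excluded.
mode: summary
seed: 11
output_dir: demo_out
screen:
  n_compounds: 320
  controls_per_role: 16
  n_replicates: 2
simulation:
  cells_per_well: 300
  baseline_percent_positive: 5.0
  hit_effect: 0.5
  planted_hits: [C0042, C0137, C0260, C0301]
  death_by_compound:
    C0301: 0.8
hits:
  z_threshold: 5.0
  min_replicates: 2
  death_cutoff: 0.60
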