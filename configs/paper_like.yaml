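# Study-shaped simulation config: 3 blocks × 5 tank temperatures ×
# 10 species × 7 biomass levels over a 60 hr trial, default truth surface
# and measured control variation. Species table, control table and tree
# default to the packaged fixtures.
mode: simulate
seed: 0
design:
  n_blocks: 3
  temperatures_C: [26, 28, 30, 32, 34]
  biomass_levels_g: [1, 2, 4, 6, 8, 10, 12]
  duration_hr: 60
noise:
  weighing_sd_g: 0.05
analysis:
  n_boot: 2000
  grid_points: 50
  bands: true
  pgls: true
  plots: false
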