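# Small demonstration study for `ploidyscope run --config configs/demo.yaml`.
# Two synthetic strain configurations, two animals each, table-level calling
# (set imaging.render: true to exercise the full rendering + segmentation
# path; it is slower but produces the same downstream tables).
seed: 1
out_dir: results/demo
cohort:
  groups:
    cJ: {strain: BALB_cJ}
    cByJ: {strain: BALB_cByJ}
  n_animals: 2
  n_cells: 400
  n_reference: 80
  cell_type: cardiomyocyte
  intensity_cv: 0.13
imaging:
  render: false
quantify:
  threshold: otsu
compare:
  metrics: [mononuclear_fraction, diploid_cell_fraction]
inference:
  patterns: [mononuclear_cm, nuclear_ploidy]
backcross:
  n_replicates: 200
  n_marker_backcrosses: 3
variants:
  n_strains: 8
  n_decoys: 120
  max_shared_panel_strains: 0
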