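# Five-class synthetic panel: hematopoietic progenitors (CD34+, reference),
# untreated KG1 (KG1_C), KG1 treated with phenylbutyrate (KG1_PB) or RG108
# (KG1_RG), mature neutrophils (NF). Three independent experiments of one
# field each, 9 cells per field.
seed: 7
output_dir: runs/panel
simulate:
  reference: CD34+
  folds:
    CD34+: 1.0
    KG1_C: 0.5
    KG1_PB: 2.0
    KG1_RG: 1.5
    NF: 0.8
  n_experiments: 3
  n_scenes_per_class: 1
  scene:
    rows: 256
    cols: 256
    n_layers: 3
    n_cells: 9
    cell_radius_range: [3.0, 5.0]
    amplitude_base: 100.0
    cell_cv: 0.2
    noise_model: gaussian
    noise_param: 2.0
    background_level: 5.0
segmentation:
  sigma_smooth: 2.0
  sigma_gradient: 2.0
  sigma_window: 2.0
  rel_threshold: 0.3
  min_distance: 4.0
  min_area: 20
stats:
  reference: CD34+
  mode: auto
  pooling: per_experiment
subtract_background: true
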