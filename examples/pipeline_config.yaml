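# Demo pipeline configuration for `neuroeit pipeline --config ... --out-dir ...`
# or neuroeit.run_pipeline(yaml.safe_load(open(...)), out_dir).
#
# Runs the full chain on a reduced slab study (a few minutes); delete the
# `study:` block to run at the full experimental scale.

stages: [simulate, demodulate, qc, reconstruct, csda, trajectories]
seed: 1

study:
  extent: [5.0, 4.0, 2.0]
  element_mm: 0.25
  n_electrodes: 19
  n_pairs: 16
  grid_mm: 0.25

phantom:
  onset_ms: 8.0
  onset_depth_um: 790.0
  peak_percent: 0.05

n_trajectories: 1000
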