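# Example pipeline configuration: simulate a small bundle and run every
# stage. Point the input path fields at real files (and set simulate: false)
# to run on your own data; see PipelineConfig for all keys and defaults.
out_dir: demo_run
simulate: true
sim:
  n_states: 2
  cells_per_state: 50
  n_genes: 60
  n_informative_genes: 10
  n_peaks: 400
  stem_fraction: 0.2
models: [rf]
learner_overrides:
  rf: {n_estimators: 100}
reps: 10
min_votes: 5
top_k: 20
k_clusters: 3
stemness_cutoff: 0.5
seed: 1
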