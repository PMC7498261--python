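# Demo pipeline configuration: synthetic dataset with one planted
# attenuation-encoding edge, M1 edge statistics, 200-permutation max-|t|
# correction.  Run with:
#   painconn run-all --config examples/demo_config.yaml --workdir scratch/demo
seed: 5
simulate:
  n_subjects: 8
  n_regions: 12
  conditions: [unmodulated, counting]
  trials_per_condition: 12
  coupled_edges: [[0, 1, -8.0]]
models: [M1]
n_perms: 200
alpha: 0.05
min_degree: 3
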