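# Miniature smoke-test scenario: two strata, seconds to run.
population:
  n_strata: 2
  stratum_cluster_counts: [30, 60]
  households_per_cluster: {mean: 8, sd: 1}
  stratum_mean: [128.0, 133.0]
  seed: 7
designs:
  - {name: M1, method: M1, clusters_per_stratum: 10}
  - {name: M2-20, method: M2, total_clusters: 20, household_fraction: 1/2}
replicates: 200
seed: 3
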