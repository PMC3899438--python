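# Anchored benchmark scenario: ten strata with fixed cluster counts and
# stratum means of X; the conventional design plus the five two-stage PPS
# scenarios.  Full run: ~34M individuals, 6 designs x 1000 replicates.
population:
  n_strata: 10
  stratum_cluster_counts: [22708, 6043, 31176, 4161, 18121, 18841, 21151, 32143, 4538, 36939]
  households_per_cluster: {mean: 50, sd: 1}
  members_per_household: [1, 6]
  stratum_mean: [131.0, 126.0, 128.3, 127.4, 131.8, 133.5, 130.0, 126.2, 129.1, 131.6]
  sigma_between_clusters: {mean: 5, sd: 0.1}
  sigma_between_households: {mean: 7, sd: 0.2}
  sigma_within_household: {mean: 10, sd: 0.2}
  threshold: 140
  seed: 1
designs:
  - {name: M1, method: M1, clusters_per_stratum: 100}
  - {name: M2-1000, method: M2, total_clusters: 1000, household_fraction: 1}
  - {name: M2-2000, method: M2, total_clusters: 2000, household_fraction: 1/2}
  - {name: M2-3000, method: M2, total_clusters: 3000, household_fraction: 1/3}
  - {name: M2-4000, method: M2, total_clusters: 4000, household_fraction: 1/4}
  - {name: M2-5000, method: M2, total_clusters: 5000, household_fraction: 1/5}
replicates: 1000
seed: 2
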