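"""Miniature populations with hand-auditable truths, for tests and demos."""

from __future__ import annotations

import numpy as np

from .population import GaussianSpec, Population, PopulationConfig, generate_population

__all__ = ["make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("toy3cluster", "single_stratum_equal", "two_strata")

# toy3cluster: one stratum, three clusters of 2/3/5 households.  Member
# counts and X values are small integers so every estimate can be checked
# by hand; 10 of the 18 values sit at or above the 140 threshold.
_TOY_MEMBERS = [[1, 2], [2, 1, 3], [1, 1, 2, 2, 3]]
_TOY_X = [
    120.0, 135.0, 150.0,                        # cluster 1 (households 1 | 2)
    110.0, 145.0, 160.0, 125.0, 140.0, 155.0,   # cluster 2 (2 | 1 | 3)
    130.0, 150.0, 115.0, 145.0, 120.0, 140.0,   # cluster 3 (1 | 1 | 2 | 2 | 3)
    135.0, 150.0, 165.0,
]


def make_fixture(kind: str, seed: int = 7) -> Population:
    """Build one of the named miniature populations.

    ``toy3cluster``
        3 clusters of 2/3/5 households, 20 individuals with enumerable X;
        exercises the two-stage weight arithmetic on a frame small enough
        for brute-force verification.
    ``single_stratum_equal``
        One stratum of 4000 identical clusters (5 households x 2 members)
        with iid X, so the closed-form variance of an equal-probability
        cluster sample applies.
    ``two_strata``
        Two unequal strata (30 and 60 clusters) from the full generator;
        exercises stratum-domain estimation under the two-stage design.
    """
    if kind == "toy3cluster":
        return Population.from_arrays(
            cluster_stratum=[0, 0, 0],
            members_per_household=_TOY_MEMBERS,
            x=_TOY_X,
            threshold=140.0,
        )
    if kind == "single_stratum_equal":
        n_clusters, hh, members = 4000, 5, 2
        rng = np.random.default_rng(seed)
        x = rng.normal(130.0, 13.0, n_clusters * hh * members)
        return Population.from_arrays(
            cluster_stratum=np.zeros(n_clusters, dtype=int),
            members_per_household=[[members] * hh] * n_clusters,
            x=x,
            threshold=140.0,
        )
    if kind == "two_strata":
        cfg = PopulationConfig(
            n_strata=2,
            stratum_cluster_counts=[30, 60],
            households_per_cluster=GaussianSpec(8.0, 1.0),
            stratum_mean=[128.0, 133.0],
            seed=seed,
        )
        return generate_population(cfg)
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
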