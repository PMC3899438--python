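"""Hierarchical finite-population generator and census (truth) summaries.

The synthetic population mimics a national household-survey frame: H strata
(prefecture-like units), each holding thousands of census enumeration areas
("clusters") of roughly 50 households, with household sizes uniform on
1..6 members.  A continuous outcome X (modelled on systolic blood pressure,
in mmHg) follows a four-level Gaussian hierarchy::

    X_hijk ~ N(mu_hij, sigma_hij^2)        individual k in household j
    mu_hij ~ N(mu_hi, sigma_hi^2)          household mean within cluster i
    mu_hi  ~ N(mu_h,  sigma_h^2)           cluster mean within stratum h
    mu_h   ~ N(130, 2.5^2)                 stratum mean (or anchored values)

with the scale parameters themselves drawn once per unit:
sigma_h ~ N(5, 0.1^2), sigma_hi ~ N(7, 0.2^2), sigma_hij ~ N(10, 0.2^2).
A binary indicator marks X >= threshold (default 140, the hypertension
cutoff).  By the law of total variance the marginal variance of X is about
2.5^2 + 5^2 + 7^2 + 10^2 = 180.25, i.e. SD ~ 13.4.

Cluster- and household-level aggregates (member count, sum of X, sum of the
indicator) are precomputed so that replicated sample estimation never has to
touch the ~3e7 individual records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "GaussianSpec",
    "PopulationConfig",
    "Population",
    "TruthSummary",
    "generate_population",
    "summarize_population",
    "REFERENCE_CLUSTER_COUNTS",
    "REFERENCE_STRATUM_MEANS",
]

# Benchmark ("anchored") configuration: per-stratum cluster counts and
# stratum means of X for the reference ten-stratum population used
# throughout the accuracy study.  Stratum sizes span the range of census
# enumeration-area counts across Japanese prefectures; the means are spread
# around 130 mmHg as in national blood-pressure surveys.
REFERENCE_CLUSTER_COUNTS: tuple[int, ...] = (
    22708, 6043, 31176, 4161, 18121, 18841, 21151, 32143, 4538, 36939,
)
REFERENCE_STRATUM_MEANS: tuple[float, ...] = (
    131.0, 126.0, 128.3, 127.4, 131.8, 133.5, 130.0, 126.2, 129.1, 131.6,
)

#: floor applied to any nonpositive draw of a scale parameter
SIGMA_FLOOR = 1e-6


class ConfigError(ValueError):
    """Invalid population or design configuration."""


@dataclass(frozen=True)
class GaussianSpec:
    """Mean/SD pair for a Gaussian hyperprior."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean):
            raise ConfigError(f"GaussianSpec.mean must be finite, got {self.mean}")
        if not (np.isfinite(self.sd) and self.sd >= 0):
            raise ConfigError(f"GaussianSpec.sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class PopulationConfig:
    """All hyperparameters of the hierarchical population generator.

    ``stratum_cluster_counts`` is either the string ``"random"`` (cluster
    counts drawn uniformly on ``cluster_count_bounds``, inclusive) or an
    explicit per-stratum list.  ``stratum_mean`` is either a
    :class:`GaussianSpec` hyperprior or an explicit per-stratum list of
    means; fixing both to the reference values gives the anchored benchmark
    population (see :meth:`reference`).
    """

    n_strata: int = 10
    stratum_cluster_counts: Union[str, Sequence[int]] = "random"
    cluster_count_bounds: tuple[int, int] = (4000, 40000)
    households_per_cluster: GaussianSpec = GaussianSpec(50.0, 1.0)
    members_per_household: tuple[int, int] = (1, 6)
    stratum_mean: Union[GaussianSpec, Sequence[float]] = GaussianSpec(130.0, 2.5)
    sigma_between_clusters: GaussianSpec = GaussianSpec(5.0, 0.1)
    sigma_between_households: GaussianSpec = GaussianSpec(7.0, 0.2)
    sigma_within_household: GaussianSpec = GaussianSpec(10.0, 0.2)
    threshold: float = 140.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strata < 1:
            raise ConfigError(f"n_strata must be >= 1, got {self.n_strata}")
        if isinstance(self.stratum_cluster_counts, str):
            if self.stratum_cluster_counts != "random":
                raise ConfigError(
                    "stratum_cluster_counts must be 'random' or an explicit "
                    f"list, got {self.stratum_cluster_counts!r}"
                )
            lo, hi = self.cluster_count_bounds
            if not (1 <= lo <= hi):
                raise ConfigError(
                    f"cluster_count_bounds must satisfy 1 <= lo <= hi, got ({lo}, {hi})"
                )
        else:
            counts = list(self.stratum_cluster_counts)
            if len(counts) != self.n_strata:
                raise ConfigError(
                    "stratum_cluster_counts: explicit list must have length "
                    f"n_strata={self.n_strata}, got {len(counts)}"
                )
            if any(int(c) < 1 for c in counts):
                raise ConfigError("stratum_cluster_counts entries must be >= 1")
        if not isinstance(self.stratum_mean, GaussianSpec):
            means = list(self.stratum_mean)
            if len(means) != self.n_strata:
                raise ConfigError(
                    "stratum_mean: explicit list must have length "
                    f"n_strata={self.n_strata}, got {len(means)}"
                )
        lo, hi = self.members_per_household
        if not (1 <= lo <= hi):
            raise ConfigError(
                f"members_per_household must satisfy 1 <= lo <= hi, got ({lo}, {hi})"
            )
        if not np.isfinite(self.threshold):
            raise ConfigError(f"threshold must be finite, got {self.threshold}")

    @classmethod
    def reference(cls, seed: int = 0, **overrides) -> "PopulationConfig":
        """The anchored benchmark configuration.

        Fixes the per-stratum cluster counts and stratum means of X to the
        reference values so that stratum weights (hence design comparisons)
        are reproducible; all scale hyperpriors keep their defaults.
        """
        kwargs = dict(
            n_strata=len(REFERENCE_CLUSTER_COUNTS),
            stratum_cluster_counts=REFERENCE_CLUSTER_COUNTS,
            stratum_mean=REFERENCE_STRATUM_MEANS,
            seed=seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class Population:
    """Columnar hierarchical population frame.

    Clusters are stored sorted by (stratum_id, cluster_id); households are
    contiguous within clusters, individuals contiguous within households.
    Identifier convention: strata are 1..H; a cluster's id is its 1-based
    position within its stratum; a household's id its 1-based position
    within its cluster.  All sampling operates on positions in this sorted
    frame.
    """

    threshold: float
    # stratum level (length H; offsets length H+1)
    stratum_mu: np.ndarray
    stratum_sigma: np.ndarray
    stratum_cluster_start: np.ndarray
    # cluster level (sorted by stratum, then cluster; offsets length C+1)
    cluster_stratum: np.ndarray
    cluster_n_households: np.ndarray
    cluster_mu: np.ndarray
    cluster_sigma: np.ndarray
    cluster_hh_start: np.ndarray
    cluster_n_members: np.ndarray
    cluster_sum_x: np.ndarray
    cluster_sum_bin: np.ndarray
    # household level
    hh_cluster: np.ndarray
    hh_n_members: np.ndarray
    hh_mu: np.ndarray
    hh_sigma: np.ndarray
    hh_sum_x: np.ndarray
    hh_sum_bin: np.ndarray
    # individual level
    individual_values: np.ndarray
    config: PopulationConfig | None = field(default=None, repr=False)

    @property
    def n_strata(self) -> int:
        return len(self.stratum_mu)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_n_households)

    @property
    def n_households(self) -> int:
        return len(self.hh_n_members)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_values)

    @property
    def binary_values(self) -> np.ndarray:
        """0/1 indicator per individual, 1 iff X >= threshold."""
        return (self.individual_values >= self.threshold).astype(np.int8)

    @property
    def hh_stratum(self) -> np.ndarray:
        return self.cluster_stratum[self.hh_cluster]

    def stratum_individuals(self) -> np.ndarray:
        """Individual count per stratum (length H)."""
        return np.add.reduceat(self.cluster_n_members, self.stratum_cluster_start[:-1])

    def stratum_households(self) -> np.ndarray:
        return np.add.reduceat(self.cluster_n_households, self.stratum_cluster_start[:-1])

    def stratum_clusters(self) -> np.ndarray:
        return np.diff(self.stratum_cluster_start)

    @classmethod
    def from_arrays(
        cls,
        cluster_stratum: Sequence[int],
        members_per_household: Sequence[Sequence[int]],
        x: Sequence[float],
        threshold: float,
        stratum_mu: Sequence[float] | None = None,
    ) -> "Population":
        """Build a population from explicit tables (fixtures, tests).

        Parameters
        ----------
        cluster_stratum
            Stratum index (0-based) per cluster, sorted and contiguous.
        members_per_household
            One inner sequence per cluster with the member count of each of
            its households.
        x
            Individual X values, household- and cluster-contiguous in the
            same order.
        """
        cluster_stratum = np.asarray(cluster_stratum, dtype=np.int32)
        if np.any(np.diff(cluster_stratum) < 0):
            raise ValueError("cluster_stratum must be sorted")
        n_strata = int(cluster_stratum.max()) + 1 if len(cluster_stratum) else 0
        stratum_cluster_start = np.searchsorted(
            cluster_stratum, np.arange(n_strata + 1)
        ).astype(np.int64)
        cluster_n_households = np.array(
            [len(m) for m in members_per_household], dtype=np.int64
        )
        hh_n_members = np.concatenate(
            [np.asarray(m, dtype=np.int64) for m in members_per_household]
        )
        hh_cluster = np.repeat(
            np.arange(len(cluster_stratum), dtype=np.int64), cluster_n_households
        )
        x = np.asarray(x, dtype=np.float64)
        if len(x) != hh_n_members.sum():
            raise ValueError("x length must equal total member count")
        hh_off = np.concatenate(([0], np.cumsum(hh_n_members)))
        hh_sum_x = np.add.reduceat(x, hh_off[:-1])
        hh_sum_bin = np.add.reduceat((x >= threshold).astype(np.int64), hh_off[:-1])
        cl_off = np.concatenate(([0], np.cumsum(cluster_n_households))).astype(np.int64)
        cluster_n_members = np.add.reduceat(hh_n_members, cl_off[:-1])
        cluster_sum_x = np.add.reduceat(hh_sum_x, cl_off[:-1])
        cluster_sum_bin = np.add.reduceat(hh_sum_bin, cl_off[:-1])
        mu = (
            np.asarray(stratum_mu, dtype=np.float64)
            if stratum_mu is not None
            else np.full(n_strata, np.nan)
        )
        return cls(
            threshold=float(threshold),
            stratum_mu=mu,
            stratum_sigma=np.full(n_strata, np.nan),
            stratum_cluster_start=stratum_cluster_start,
            cluster_stratum=cluster_stratum,
            cluster_n_households=cluster_n_households,
            cluster_mu=np.full(len(cluster_stratum), np.nan),
            cluster_sigma=np.full(len(cluster_stratum), np.nan),
            cluster_hh_start=cl_off,
            cluster_n_members=cluster_n_members,
            cluster_sum_x=cluster_sum_x,
            cluster_sum_bin=cluster_sum_bin,
            hh_cluster=hh_cluster,
            hh_n_members=hh_n_members,
            hh_mu=np.full(len(hh_n_members), np.nan),
            hh_sigma=np.full(len(hh_n_members), np.nan),
            hh_sum_x=hh_sum_x,
            hh_sum_bin=hh_sum_bin,
            individual_values=x,
        )

    def validate(self) -> None:
        """Check structural invariants; raises AssertionError on violation."""
        assert self.n_individuals == int(self.hh_n_members.sum())
        assert self.n_households == int(self.cluster_n_households.sum())
        assert np.all(self.cluster_n_households >= 1)
        assert np.all(self.hh_n_members >= 1)
        assert self.cluster_hh_start[-1] == self.n_households
        assert self.stratum_cluster_start[-1] == self.n_clusters
        # aggregates match a brute-force recomputation on a subsample
        rng = np.random.default_rng(0)
        take = min(100, self.n_clusters)
        off = np.concatenate(([0], np.cumsum(self.hh_n_members)))
        for c in rng.choice(self.n_clusters, size=take, replace=False):
            h0, h1 = self.cluster_hh_start[c], self.cluster_hh_start[c + 1]
            xs = self.individual_values[off[h0]: off[h1]]
            assert len(xs) == self.cluster_n_members[c]
            assert np.isclose(xs.sum(), self.cluster_sum_x[c], rtol=1e-9)
            assert (xs >= self.threshold).sum() == self.cluster_sum_bin[c]


def _draw_sigma(rng: np.random.Generator, spec: GaussianSpec, size=None) -> np.ndarray:
    draws = rng.normal(spec.mean, spec.sd, size)
    return np.maximum(draws, SIGMA_FLOOR)


def generate_population(config: PopulationConfig) -> Population:
    """Generate the hierarchical population described by ``config``.

    Deterministic given the config (including its seed): strata are
    generated in order 1..H, and within each stratum the draw order is
    cluster count (if random), stratum mean (if random), stratum scale,
    cluster means, cluster scales, household counts, household means,
    household scales, member counts, individual X values.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    H = config.n_strata
    explicit_counts = not isinstance(config.stratum_cluster_counts, str)
    explicit_means = not isinstance(config.stratum_mean, GaussianSpec)

    stratum_mu = np.empty(H)
    stratum_sigma = np.empty(H)
    counts = np.empty(H, dtype=np.int64)

    cl_stratum, cl_nhh, cl_mu, cl_sigma = [], [], [], []
    hh_nmem, hh_mu, hh_sigma, hh_sx, hh_sb = [], [], [], [], []
    xs = []

    mlo, mhi = config.members_per_household
    for h in range(H):
        if explicit_counts:
            Nh = int(config.stratum_cluster_counts[h])
        else:
            lo, hi = config.cluster_count_bounds
            Nh = int(rng.integers(lo, hi + 1))
        counts[h] = Nh
        if explicit_means:
            mu_h = float(config.stratum_mean[h])
        else:
            mu_h = float(rng.normal(config.stratum_mean.mean, config.stratum_mean.sd))
        sig_h = float(_draw_sigma(rng, config.sigma_between_clusters))
        stratum_mu[h], stratum_sigma[h] = mu_h, sig_h

        mu_hi = rng.normal(mu_h, sig_h, Nh)
        sig_hi = _draw_sigma(rng, config.sigma_between_households, Nh)
        n_hh = np.maximum(
            np.rint(
                rng.normal(
                    config.households_per_cluster.mean,
                    config.households_per_cluster.sd,
                    Nh,
                )
            ).astype(np.int64),
            1,
        )
        tot_hh = int(n_hh.sum())
        mu_hij = rng.normal(np.repeat(mu_hi, n_hh), np.repeat(sig_hi, n_hh))
        sig_hij = _draw_sigma(rng, config.sigma_within_household, tot_hh)
        n_mem = rng.integers(mlo, mhi + 1, tot_hh)
        x = rng.normal(np.repeat(mu_hij, n_mem), np.repeat(sig_hij, n_mem))

        off = np.concatenate(([0], np.cumsum(n_mem)))[:-1]
        sx = np.add.reduceat(x, off)
        sb = np.add.reduceat((x >= config.threshold).astype(np.int64), off)

        cl_stratum.append(np.full(Nh, h, dtype=np.int32))
        cl_nhh.append(n_hh)
        cl_mu.append(mu_hi)
        cl_sigma.append(sig_hi)
        hh_nmem.append(n_mem)
        hh_mu.append(mu_hij)
        hh_sigma.append(sig_hij)
        hh_sx.append(sx)
        hh_sb.append(sb)
        xs.append(x)

    cluster_n_households = np.concatenate(cl_nhh)
    cluster_hh_start = np.concatenate(
        ([0], np.cumsum(cluster_n_households))
    ).astype(np.int64)
    hh_n_members = np.concatenate(hh_nmem)
    hh_sum_x = np.concatenate(hh_sx)
    hh_sum_bin = np.concatenate(hh_sb)
    cluster_n_members = np.add.reduceat(hh_n_members, cluster_hh_start[:-1])
    cluster_sum_x = np.add.reduceat(hh_sum_x, cluster_hh_start[:-1])
    cluster_sum_bin = np.add.reduceat(hh_sum_bin, cluster_hh_start[:-1])

    return Population(
        threshold=float(config.threshold),
        stratum_mu=stratum_mu,
        stratum_sigma=stratum_sigma,
        stratum_cluster_start=np.concatenate(([0], np.cumsum(counts))).astype(np.int64),
        cluster_stratum=np.concatenate(cl_stratum),
        cluster_n_households=cluster_n_households,
        cluster_mu=np.concatenate(cl_mu),
        cluster_sigma=np.concatenate(cl_sigma),
        cluster_hh_start=cluster_hh_start,
        cluster_n_members=cluster_n_members,
        cluster_sum_x=cluster_sum_x,
        cluster_sum_bin=cluster_sum_bin,
        hh_cluster=np.repeat(
            np.arange(len(cluster_n_households), dtype=np.int64),
            cluster_n_households,
        ),
        hh_n_members=hh_n_members,
        hh_mu=np.concatenate(hh_mu),
        hh_sigma=np.concatenate(hh_sigma),
        hh_sum_x=hh_sum_x,
        hh_sum_bin=hh_sum_bin,
        individual_values=np.concatenate(xs),
        config=config,
    )


@dataclass
class TruthSummary:
    """Census summary of the population: the benchmark for RMSE.

    ``table`` has one row per stratum (index 1..H) plus a ``"total"`` row,
    with columns clusters, households, individuals, mean_x,
    prop_ge_threshold.  ``overall_sd`` is the SD of X over all individuals.
    """

    table: pd.DataFrame
    overall_sd: float

    @property
    def stratum_mean_x(self) -> np.ndarray:
        return self.table["mean_x"].to_numpy()[:-1]

    @property
    def stratum_prop(self) -> np.ndarray:
        return self.table["prop_ge_threshold"].to_numpy()[:-1]

    @property
    def total_mean_x(self) -> float:
        return float(self.table.loc["total", "mean_x"])

    @property
    def total_prop(self) -> float:
        return float(self.table.loc["total", "prop_ge_threshold"])

    def to_csv(self, path) -> None:
        out = self.table.reset_index(names="stratum_id")
        out.to_csv(path, index=False)


def summarize_population(pop: Population) -> TruthSummary:
    """Exact per-stratum and total counts, means of X, and proportions."""
    if pop.n_individuals == 0:
        raise ValueError("cannot summarize an empty population")
    starts = pop.stratum_cluster_start[:-1]
    clusters = pop.stratum_clusters()
    households = pop.stratum_households()
    individuals = pop.stratum_individuals()
    sum_x = np.add.reduceat(pop.cluster_sum_x, starts)
    sum_b = np.add.reduceat(pop.cluster_sum_bin, starts)
    rows = pd.DataFrame(
        {
            "clusters": clusters,
            "households": households,
            "individuals": individuals,
            "mean_x": sum_x / individuals,
            "prop_ge_threshold": sum_b / individuals,
        },
        index=pd.Index(range(1, pop.n_strata + 1), name="stratum_id"),
    )
    total = pd.DataFrame(
        {
            "clusters": [clusters.sum()],
            "households": [households.sum()],
            "individuals": [individuals.sum()],
            "mean_x": [sum_x.sum() / individuals.sum()],
            "prop_ge_threshold": [sum_b.sum() / individuals.sum()],
        },
        index=pd.Index(["total"], name="stratum_id"),
    )
    table = pd.concat([rows, total])
    return TruthSummary(table=table, overall_sd=float(pop.individual_values.std()))
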