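"""Sample designs and their primitive selection algorithms.

Two designs are implemented:

* **Method 1** (conventional): within each stratum, a constant number of
  clusters is drawn by systematic random sampling without replacement and
  every household of a selected cluster is enumerated.  Design weights are
  stratum constants: the inverse of the realized fraction of individuals
  sampled in the stratum.

* **Method 2** (two-stage PPS): clusters are drawn across all strata from
  the frame sorted by (stratum, cluster) with probability proportional to
  their household count, using fixed-take systematic PPS on the cumulative
  size scale (the sort gives implicit stratification); then households are
  subsampled within each selected cluster by simple random sampling without
  replacement at a fixed fraction f.  A household's weight is the inverse
  of the product of its cluster's inclusion probability and the realized
  second-stage fraction m/N, so the estimated household total is exactly
  design-unbiased.

The primitives (`systematic_sample`, `systematic_pps`, `srswor`,
`second_stage_count`) are exposed separately so their inclusion
probabilities can be verified by enumeration on small frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, Union

import numpy as np

from .population import ConfigError, Population

__all__ = [
    "DesignSpec",
    "SampleDraw",
    "systematic_positions",
    "systematic_sample",
    "systematic_pps",
    "srswor",
    "second_stage_count",
    "draw_method1",
    "draw_method2",
]

IntervalRule = Literal["fractional", "ceil", "floor"]
Rounding = Literal["ceil", "nearest"]

# The five standard scenarios for the two-stage design: total clusters n
# paired with the household sampling fraction f so that the expected number
# of sampled households stays near 50 000 (n * 50 * f ~ const).
STANDARD_M2_SCENARIOS: tuple[tuple[int, Fraction], ...] = (
    (1000, Fraction(1)),
    (2000, Fraction(1, 2)),
    (3000, Fraction(1, 3)),
    (4000, Fraction(1, 4)),
    (5000, Fraction(1, 5)),
)


@dataclass(frozen=True)
class DesignSpec:
    """Specification of one sample design.

    For ``method="M1"`` only ``clusters_per_stratum`` and ``interval_rule``
    apply; for ``method="M2"`` only ``total_clusters``,
    ``household_fraction`` and ``household_rounding`` apply.
    """

    method: Literal["M1", "M2"]
    name: str = ""
    clusters_per_stratum: int = 100
    interval_rule: IntervalRule = "fractional"
    total_clusters: int = 1000
    household_fraction: Fraction = Fraction(1)
    household_rounding: Rounding = "ceil"

    def __post_init__(self) -> None:
        if self.method not in ("M1", "M2"):
            raise ConfigError(f"method must be 'M1' or 'M2', got {self.method!r}")
        if self.method == "M1":
            if self.clusters_per_stratum < 1:
                raise ConfigError("clusters_per_stratum must be >= 1")
            if self.interval_rule not in ("fractional", "ceil", "floor"):
                raise ConfigError(f"unknown interval_rule {self.interval_rule!r}")
        else:
            if self.total_clusters < 1:
                raise ConfigError("total_clusters must be >= 1")
            f = Fraction(self.household_fraction)
            if not (0 < f <= 1):
                raise ConfigError(f"household_fraction must be in (0, 1], got {f}")
            if self.household_rounding not in ("ceil", "nearest"):
                raise ConfigError(f"unknown household_rounding {self.household_rounding!r}")
        if not self.name:
            object.__setattr__(self, "name", self._default_name())

    def _default_name(self) -> str:
        if self.method == "M1":
            return "M1"
        return f"M2-{self.total_clusters}"

    @classmethod
    def method1(cls, clusters_per_stratum: int = 100,
                interval_rule: IntervalRule = "fractional", name: str = "") -> "DesignSpec":
        return cls(method="M1", clusters_per_stratum=clusters_per_stratum,
                   interval_rule=interval_rule, name=name)

    @classmethod
    def method2(cls, total_clusters: int, household_fraction=Fraction(1),
                household_rounding: Rounding = "ceil", name: str = "") -> "DesignSpec":
        return cls(method="M2", total_clusters=total_clusters,
                   household_fraction=Fraction(household_fraction),
                   household_rounding=household_rounding, name=name)

    @classmethod
    def standard_scenarios(cls) -> list["DesignSpec"]:
        """Method 1 plus the five standard Method 2 scenarios."""
        specs = [cls.method1()]
        specs += [cls.method2(n, f) for n, f in STANDARD_M2_SCENARIOS]
        return specs


@dataclass
class SampleDraw:
    """One realized sample with its design weights.

    ``cluster_indices`` are positions in the population's sorted cluster
    frame.  For Method 1 households are implicitly *all* households of the
    selected clusters and weights are the per-stratum constants in
    ``stratum_weights``.  For Method 2 the selected households are listed
    explicitly with one weight each (individuals inherit their household's
    weight).
    """

    method: str
    cluster_indices: np.ndarray
    cluster_incl_prob: np.ndarray
    # Method 1
    stratum_weights: np.ndarray | None = None
    # Method 2
    household_indices: np.ndarray | None = None
    household_weights: np.ndarray | None = None
    m_per_cluster: np.ndarray | None = None
    # realized per-stratum sample sizes (length H each)
    n_clusters_by_stratum: np.ndarray | None = None
    n_households_by_stratum: np.ndarray | None = None
    n_individuals_by_stratum: np.ndarray | None = None


def systematic_positions(frame_size: int, n: int,
                         interval_rule: IntervalRule, start: float) -> np.ndarray:
    """Positions (0-based) selected by systematic sampling from a given start.

    Under the ``fractional`` rule the interval is k = frame_size/n (real),
    ``start`` must lie in (0, k], and position ceil(start + j*k) - 1 is
    taken for j = 0..n-1 — always exactly n distinct positions.  Under the
    integer rules the interval is ceil or floor of frame_size/n, ``start``
    is an integer in 1..k, and every k-th position is taken to the end of
    the frame, so the realized size may deviate from n.
    """
    if interval_rule == "fractional":
        k = frame_size / n
        if not (0 < start <= k):
            raise ValueError(f"start must be in (0, {k}], got {start}")
        pos = np.ceil(start + k * np.arange(n)).astype(np.int64) - 1
        return np.minimum(pos, frame_size - 1)
    if interval_rule == "ceil":
        k = -(-frame_size // n)
    elif interval_rule == "floor":
        k = frame_size // n
    else:
        raise ValueError(f"unknown interval_rule {interval_rule!r}")
    s = int(start)
    if not (1 <= s <= k):
        raise ValueError(f"integer start must be in 1..{k}, got {start}")
    return np.arange(s - 1, frame_size, k, dtype=np.int64)


def systematic_sample(frame_size: int, n: int, rng: np.random.Generator,
                      interval_rule: IntervalRule = "fractional") -> np.ndarray:
    """Systematic random sample without replacement; 0-based positions."""
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    if n > frame_size:
        raise ValueError(f"sample size {n} exceeds frame size {frame_size}")
    if interval_rule == "fractional":
        k = frame_size / n
        start = k * (1.0 - rng.random())          # uniform on (0, k]
    else:
        k = -(-frame_size // n) if interval_rule == "ceil" else frame_size // n
        start = int(rng.integers(1, k + 1))
    return systematic_positions(frame_size, n, interval_rule, start)


def systematic_pps(sizes: np.ndarray, n: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-take systematic PPS sampling on the cumulative size scale.

    Returns exactly ``n`` distinct 0-based positions together with the
    first-order inclusion probabilities pi_i = n * size_i / sum(sizes).
    Units with pi_i > 1 (certainty units) are rejected: lower ``n`` or
    remove take-all units before calling.
    """
    sizes = np.asarray(sizes)
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    if np.any(sizes <= 0):
        raise ValueError("all size measures must be positive")
    total = sizes.sum()
    if n * sizes.max() > total:
        raise ValueError(
            f"certainty units present: n={n} times max size {sizes.max()} exceeds "
            f"total size {total}; lower n (take-all units are not supported)"
        )
    k = total / n
    u = k * (1.0 - rng.random())                  # uniform on (0, k]
    points = u + k * np.arange(n)
    cum = np.cumsum(sizes)
    pos = np.searchsorted(cum, points, side="left")
    pos = np.minimum(pos, len(sizes) - 1)
    probs = n * sizes / total
    return pos, probs


def srswor(frame_size: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """Simple random sample without replacement; sorted 0-based positions."""
    if m < 1:
        raise ValueError(f"sample size must be >= 1, got {m}")
    if m > frame_size:
        raise ValueError(f"sample size {m} exceeds frame size {frame_size}")
    return np.sort(rng.choice(frame_size, size=m, replace=False))


def second_stage_count(n_households: int, f: Fraction,
                       rounding: Rounding = "ceil") -> int:
    """Number of households to draw from a cluster of ``n_households`` at fraction f."""
    if n_households < 1:
        raise ValueError("n_households must be >= 1")
    f = Fraction(f)
    if not (0 < f <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {f}")
    num, den = f.numerator, f.denominator
    if rounding == "ceil":
        m = -(-n_households * num // den)
    elif rounding == "nearest":
        m = (2 * n_households * num + den) // (2 * den)
    else:
        raise ValueError(f"unknown rounding {rounding!r}")
    return int(min(max(m, 1), n_households))


def _stratum_counts(pop: Population, clusters: np.ndarray,
                    hh: np.ndarray, ind: np.ndarray) -> tuple[np.ndarray, ...]:
    strat = pop.cluster_stratum[clusters]
    H = pop.n_strata
    return (
        np.bincount(strat, minlength=H).astype(np.int64),
        np.bincount(strat, weights=hh, minlength=H).astype(np.int64),
        np.bincount(strat, weights=ind, minlength=H).astype(np.int64),
    )


def draw_method1(pop: Population, spec: DesignSpec,
                 rng: np.random.Generator) -> SampleDraw:
    """Stratified systematic cluster sample with full household take.

    Per stratum, ``clusters_per_stratum`` clusters are drawn systematically
    from the stratum's cluster list; all their households (and members) are
    included.  The individual-level weight in stratum h is
    N_h / n_h — stratum individual count over realized sampled count — so
    the weighted sample reproduces each stratum's population size exactly.
    """
    if spec.method != "M1":
        raise ConfigError("draw_method1 requires an M1 spec")
    per = spec.clusters_per_stratum
    counts = pop.stratum_clusters()
    if per > counts.min():
        raise ConfigError(
            f"clusters_per_stratum={per} exceeds the smallest stratum "
            f"({int(counts.min())} clusters)"
        )
    sel = []
    for h in range(pop.n_strata):
        lo = pop.stratum_cluster_start[h]
        pos = systematic_sample(int(counts[h]), per, rng, spec.interval_rule)
        sel.append(lo + pos)
    clusters = np.concatenate(sel)
    n_cl, n_hh, n_ind = _stratum_counts(
        pop, clusters,
        pop.cluster_n_households[clusters], pop.cluster_n_members[clusters],
    )
    pop_ind = pop.stratum_individuals()
    weights = pop_ind / n_ind
    strat = pop.cluster_stratum[clusters]
    return SampleDraw(
        method="M1",
        cluster_indices=clusters,
        cluster_incl_prob=(per / counts)[strat],
        stratum_weights=weights,
        n_clusters_by_stratum=n_cl,
        n_households_by_stratum=n_hh,
        n_individuals_by_stratum=n_ind,
    )


def _select_households(pop: Population, clusters: np.ndarray, m: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """SRSWOR of m[c] households within each selected cluster, vectorized.

    Assigns an independent uniform key to every household of every selected
    cluster and keeps the m smallest keys per cluster — equivalent to
    simple random sampling without replacement within each cluster.
    """
    N = pop.cluster_n_households[clusters]
    if np.array_equal(m, N):
        # full take: households are contiguous, no randomness needed
        seg = np.repeat(np.cumsum(N) - N, N)
        return np.repeat(pop.cluster_hh_start[clusters], N) + np.arange(N.sum()) - seg
    total = int(N.sum())
    seg_start = np.repeat(np.cumsum(N) - N, N)
    within = np.arange(total) - seg_start
    hh_global = np.repeat(pop.cluster_hh_start[clusters], N) + within
    keys = rng.random(total)
    seg_id = np.repeat(np.arange(len(clusters)), N)
    order = np.lexsort((keys, seg_id))
    ranked = hh_global[order]
    keep = within < np.repeat(m, N)   # rank within segment after the sort
    return ranked[keep]


def draw_method2(pop: Population, spec: DesignSpec,
                 rng: np.random.Generator) -> SampleDraw:
    """Two-stage sample: systematic PPS of clusters, then SRSWOR of households.

    Clusters are drawn across all strata from the frame sorted by
    (stratum, cluster) with probability proportional to household count;
    m = ceil(f * N) households are then drawn from each selected cluster.
    Each selected household gets weight 1 / (pi_cluster * m/N), using the
    realized second-stage fraction m/N rather than the nominal f.
    """
    if spec.method != "M2":
        raise ConfigError("draw_method2 requires an M2 spec")
    clusters, probs_all = systematic_pps(
        pop.cluster_n_households, spec.total_clusters, rng
    )
    pi = probs_all[clusters]
    N = pop.cluster_n_households[clusters]
    f = Fraction(spec.household_fraction)
    num, den = f.numerator, f.denominator
    if spec.household_rounding == "ceil":
        m = -(-N * num // den)
    else:
        m = (2 * N * num + den) // (2 * den)
    m = np.minimum(np.maximum(m, 1), N)
    hh_idx = _select_households(pop, clusters, m, rng)
    w_cluster = 1.0 / (pi * (m / N))
    hh_w = np.repeat(w_cluster, m)
    hh_members = pop.hh_n_members[hh_idx]
    # realized sizes by stratum
    strat_cl = pop.cluster_stratum[clusters]
    H = pop.n_strata
    ind_per_cluster = np.add.reduceat(
        hh_members, np.concatenate(([0], np.cumsum(m)))[:-1]
    )
    return SampleDraw(
        method="M2",
        cluster_indices=clusters,
        cluster_incl_prob=pi,
        household_indices=hh_idx,
        household_weights=hh_w,
        m_per_cluster=m,
        n_clusters_by_stratum=np.bincount(strat_cl, minlength=H).astype(np.int64),
        n_households_by_stratum=np.bincount(
            strat_cl, weights=m, minlength=H
        ).astype(np.int64),
        n_individuals_by_stratum=np.bincount(
            strat_cl, weights=ind_per_cluster, minlength=H
        ).astype(np.int64),
    )
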