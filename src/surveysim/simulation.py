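"""Replicated sampling, Monte-Carlo RMSE, and design comparison tables.

Accuracy of a design is summarised by the root-mean-squared error of its
estimator across R independent sample draws against the census truth:
RMSE = sqrt(mean((estimate - truth)^2)), which decomposes as
RMSE^2 = variance + bias^2 with the population-style (divisor R) variance.
Replicates use independent named RNG streams spawned from a root seed, so
any execution order yields identical summaries and individual replicates
can be regenerated in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .designs import DesignSpec, draw_method1, draw_method2
from .estimation import estimate
from .population import Population, TruthSummary, summarize_population

__all__ = ["ReplicationSummary", "DesignComparison", "rmse",
           "run_replications", "compare_designs"]


def rmse(estimates, truth: float) -> float:
    """Root-mean-squared error of a sequence of estimates around the truth."""
    estimates = np.asarray(estimates, dtype=np.float64)
    if estimates.size == 0:
        raise ValueError("rmse requires at least one estimate")
    if not np.isfinite(truth):
        raise ValueError("truth must be finite")
    return float(np.sqrt(np.mean((estimates - truth) ** 2)))


def replicate_rng(seed: int, stream: int, replicate: int) -> np.random.Generator:
    """Independent RNG for one (design stream, replicate) pair."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(stream, replicate))
    )


@dataclass
class ReplicationSummary:
    """Accuracy and sample-size summary of R replicated draws of one design.

    ``accuracy`` has one row per (estimand, stratum/total) with columns
    truth, mean, sd (divisor R-1), bias, rmse.  ``sample_sizes`` holds the
    average realized clusters/households/individuals per stratum and in
    total.  Raw per-replicate estimates are retained in ``estimates`` for
    diagnostics (columns: estimand x stratum).
    """

    scenario: str
    replicates: int
    seed: int
    stream: int
    accuracy: pd.DataFrame
    sample_sizes: pd.DataFrame
    estimates: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    n_empty_domains: int = 0

    def total_rmse(self, estimand: str = "mean_x") -> float:
        sub = self.accuracy
        row = sub[(sub["estimand"] == estimand) & (sub["stratum_id"] == "total")]
        return float(row["rmse"].iloc[0])

    def total_rmse_se(self, estimand: str = "mean_x") -> float:
        """Approximate Monte-Carlo SE of the RMSE estimate (CV ~ 1/sqrt(2R))."""
        return self.total_rmse(estimand) / np.sqrt(2 * self.replicates)


def _summarize(est: np.ndarray, truth: np.ndarray) -> pd.DataFrame:
    """Per-column mean/sd/bias/rmse of an (R, H+1) estimate matrix."""
    mean = np.nanmean(est, axis=0)
    sd = np.nanstd(est, axis=0, ddof=1) if est.shape[0] > 1 else np.zeros(est.shape[1])
    bias = mean - truth
    rm = np.sqrt(np.nanmean((est - truth) ** 2, axis=0))
    return pd.DataFrame({"truth": truth, "mean": mean, "sd": sd,
                         "bias": bias, "rmse": rm})


def run_replications(pop: Population, spec: DesignSpec, R: int, seed: int,
                     stream: int = 0,
                     truth: TruthSummary | None = None) -> ReplicationSummary:
    """Draw R independent samples under ``spec`` and summarise accuracy.

    ``stream`` distinguishes designs sharing a root seed (replicate r of
    design stream s uses the RNG spawned at key (s, r)).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if truth is None:
        truth = summarize_population(pop)
    H = pop.n_strata
    est_mean = np.empty((R, H + 1))
    est_prop = np.empty((R, H + 1))
    sizes = np.zeros((3, H))          # clusters, households, individuals
    n_empty = 0
    for r in range(R):
        rng = replicate_rng(seed, stream, r)
        try:
            if spec.method == "M1":
                draw = draw_method1(pop, spec, rng)
            else:
                draw = draw_method2(pop, spec, rng)
            es = estimate(draw, pop)
        except Exception as exc:
            raise RuntimeError(f"replicate {r} of scenario {spec.name!r} failed") from exc
        est_mean[r, :H] = es.stratum_mean_x
        est_mean[r, H] = es.total_mean_x
        est_prop[r, :H] = es.stratum_prop
        est_prop[r, H] = es.total_prop
        n_empty += int(np.isnan(es.stratum_mean_x).sum())
        sizes[0] += es.n_clusters_by_stratum
        sizes[1] += es.n_households_by_stratum
        sizes[2] += es.n_individuals_by_stratum
    truth_vec_mean = np.append(truth.stratum_mean_x, truth.total_mean_x)
    truth_vec_prop = np.append(truth.stratum_prop, truth.total_prop)
    labels = [str(i) for i in range(1, H + 1)] + ["total"]
    acc_mean = _summarize(est_mean, truth_vec_mean)
    acc_prop = _summarize(est_prop, truth_vec_prop)
    for df, name in ((acc_mean, "mean_x"), (acc_prop, "prop_ge_threshold")):
        df.insert(0, "stratum_id", labels)
        df.insert(0, "estimand", name)
    accuracy = pd.concat([acc_mean, acc_prop], ignore_index=True)
    avg = sizes / R
    sample_sizes = pd.DataFrame(
        {
            "clusters": np.append(avg[0], avg[0].sum()),
            "households": np.append(avg[1], avg[1].sum()),
            "individuals": np.append(avg[2], avg[2].sum()),
        },
        index=pd.Index(labels, name="stratum_id"),
    )
    return ReplicationSummary(
        scenario=spec.name, replicates=R, seed=seed, stream=stream,
        accuracy=accuracy, sample_sizes=sample_sizes,
        estimates={"mean_x": est_mean, "prop_ge_threshold": est_prop},
        n_empty_domains=n_empty,
    )


@dataclass
class DesignComparison:
    """RMSE tables across scenarios plus percent change versus the baseline.

    ``rmse_mean_x`` and ``rmse_prop`` have one row per stratum plus a
    total row and one column per scenario.  ``pct_change_total`` gives
    100 * (rmse_scenario - rmse_baseline) / rmse_baseline for the total
    row, baseline being the first scenario in the list.
    """

    summaries: list[ReplicationSummary]
    rmse_mean_x: pd.DataFrame
    rmse_prop: pd.DataFrame
    sample_sizes: pd.DataFrame
    pct_change_total: pd.DataFrame

    def to_csv(self, rmse_path, sizes_path) -> None:
        blocks = pd.concat(
            {"mean_x": self.rmse_mean_x, "prop_ge_threshold": self.rmse_prop}, axis=1
        )
        blocks.to_csv(rmse_path)
        self.sample_sizes.to_csv(sizes_path)

    def to_json_summary(self, R: int, seed: int, config_hash: str = "") -> str:
        payload = {
            "replicates": R,
            "seed": seed,
            "config_hash": config_hash,
            "scenarios": [s.scenario for s in self.summaries],
            "total_rmse_mean_x": {
                s.scenario: s.total_rmse("mean_x") for s in self.summaries
            },
            "total_rmse_prop": {
                s.scenario: s.total_rmse("prop_ge_threshold") for s in self.summaries
            },
            "pct_change_total_mean_x": self.pct_change_total["mean_x"].to_dict(),
        }
        return json.dumps(payload, indent=2)


def compare_designs(pop: Population, specs: list[DesignSpec], R: int,
                    seed: int) -> DesignComparison:
    """Run every design for R replicates and tabulate RMSE side by side."""
    truth = summarize_population(pop)
    summaries = [
        run_replications(pop, spec, R, seed, stream=i, truth=truth)
        for i, spec in enumerate(specs)
    ]
    def pull(estimand: str) -> pd.DataFrame:
        cols = {}
        for s in summaries:
            sub = s.accuracy[s.accuracy["estimand"] == estimand]
            cols[s.scenario] = sub.set_index("stratum_id")["rmse"]
        return pd.DataFrame(cols)

    rmse_mean = pull("mean_x")
    rmse_prop = pull("prop_ge_threshold")
    base = summaries[0]
    pct = pd.DataFrame(
        {
            "mean_x": {
                s.scenario: 100.0 * (s.total_rmse("mean_x") / base.total_rmse("mean_x") - 1.0)
                for s in summaries
            },
            "prop_ge_threshold": {
                s.scenario: 100.0
                * (s.total_rmse("prop_ge_threshold") / base.total_rmse("prop_ge_threshold") - 1.0)
                for s in summaries
            },
        }
    )
    sizes = pd.concat({s.scenario: s.sample_sizes for s in summaries}, axis=1)
    return DesignComparison(
        summaries=summaries,
        rmse_mean_x=rmse_mean,
        rmse_prop=rmse_prop,
        sample_sizes=sizes,
        pct_change_total=pct,
    )
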