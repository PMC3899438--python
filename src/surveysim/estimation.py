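"""Design-weighted point estimation of means and proportions.

Estimates use the Hajek (weighted-ratio) form sum(w*x)/sum(w), the form
survey software produces for means and proportions of complex samples.
Under Method 1 the weights are stratum constants whose sum reproduces each
stratum's population size, so the Hajek and Horvitz-Thompson forms
coincide there.  Under Method 2 the per-stratum figures are *domain*
estimates: strata are not first-stage sampling strata of that design, so a
draw may in principle contain no household from some stratum, in which
case the domain estimate is NaN (the simulation layer counts these).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .designs import SampleDraw
from .population import Population

__all__ = ["EstimateSet", "weighted_mean", "weighted_proportion", "estimate"]


def weighted_mean(values, weights) -> float:
    """Hajek weighted mean sum(w*x) / sum(w)."""
    values = np.asarray(values, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if values.size == 0:
        raise ValueError("weighted_mean requires at least one observation")
    if values.shape != weights.shape:
        raise ValueError("values and weights must have the same length")
    if np.any(weights <= 0) or not np.all(np.isfinite(weights)):
        raise ValueError("weights must be positive and finite")
    return float(np.sum(weights * values) / np.sum(weights))


def weighted_proportion(indicators, weights) -> float:
    """Weighted proportion of a 0/1 indicator; a weighted mean with a domain check."""
    indicators = np.asarray(indicators)
    if not np.isin(indicators, (0, 1)).all():
        raise ValueError("indicators must be 0/1")
    return weighted_mean(indicators, weights)


@dataclass
class EstimateSet:
    """Point estimates from one draw: per-stratum arrays plus totals."""

    stratum_mean_x: np.ndarray
    stratum_prop: np.ndarray
    total_mean_x: float
    total_prop: float
    n_clusters_by_stratum: np.ndarray
    n_households_by_stratum: np.ndarray
    n_individuals_by_stratum: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        H = len(self.stratum_mean_x)
        idx = pd.Index(list(range(1, H + 1)) + ["total"], name="stratum_id")
        return pd.DataFrame(
            {
                "mean_x": np.append(self.stratum_mean_x, self.total_mean_x),
                "prop_ge_threshold": np.append(self.stratum_prop, self.total_prop),
                "clusters": np.append(
                    self.n_clusters_by_stratum, self.n_clusters_by_stratum.sum()
                ),
                "households": np.append(
                    self.n_households_by_stratum, self.n_households_by_stratum.sum()
                ),
                "individuals": np.append(
                    self.n_individuals_by_stratum, self.n_individuals_by_stratum.sum()
                ),
            },
            index=idx,
        )


def estimate(draw: SampleDraw, pop: Population) -> EstimateSet:
    """Weighted means of X and proportions of X >= threshold, per stratum and total.

    Works entirely from the population's precomputed household and cluster
    aggregates: households are always sampled intact, so household sums of
    X and of the indicator are sufficient statistics.
    """
    H = pop.n_strata
    if draw.method == "M1":
        clusters = draw.cluster_indices
        strat = pop.cluster_stratum[clusters]
        sx = np.bincount(strat, weights=pop.cluster_sum_x[clusters], minlength=H)
        sb = np.bincount(strat, weights=pop.cluster_sum_bin[clusters], minlength=H)
        sn = np.bincount(strat, weights=pop.cluster_n_members[clusters], minlength=H)
        if np.any(sn == 0):
            raise ValueError("Method 1 draw left a stratum empty")
        mean_h = sx / sn
        prop_h = sb / sn
        # constant within-stratum weights: weighted total = pop size per stratum
        w = draw.stratum_weights
        total_mean = float(np.sum(w * sx) / np.sum(w * sn))
        total_prop = float(np.sum(w * sb) / np.sum(w * sn))
    elif draw.method == "M2":
        hh = draw.household_indices
        if hh is None:
            raise ValueError("M2 draw carries no household indices")
        if len(hh) == 0 or hh.max() >= pop.n_households:
            raise ValueError("draw does not match this population")
        w = draw.household_weights
        strat = pop.cluster_stratum[pop.hh_cluster[hh]]
        wn = w * pop.hh_n_members[hh]
        wx = w * pop.hh_sum_x[hh]
        wb = w * pop.hh_sum_bin[hh]
        den = np.bincount(strat, weights=wn, minlength=H)
        num_x = np.bincount(strat, weights=wx, minlength=H)
        num_b = np.bincount(strat, weights=wb, minlength=H)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_h = np.where(den > 0, num_x / den, np.nan)
            prop_h = np.where(den > 0, num_b / den, np.nan)
        total_mean = float(wx.sum() / wn.sum())
        total_prop = float(wb.sum() / wn.sum())
    else:
        raise ValueError(f"unknown draw method {draw.method!r}")
    return EstimateSet(
        stratum_mean_x=mean_h,
        stratum_prop=prop_h,
        total_mean_x=total_mean,
        total_prop=total_prop,
        n_clusters_by_stratum=draw.n_clusters_by_stratum,
        n_households_by_stratum=draw.n_households_by_stratum,
        n_individuals_by_stratum=draw.n_individuals_by_stratum,
    )
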