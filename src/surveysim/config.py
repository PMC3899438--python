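"""Scenario-file parsing: population, designs, replication settings.

A scenario file is YAML with four top-level sections::

    population:                      # -> PopulationConfig
      n_strata: 10
      stratum_cluster_counts: random # or an explicit per-stratum list
      cluster_count_bounds: [4000, 40000]
      households_per_cluster: {mean: 50, sd: 1}
      members_per_household: [1, 6]
      stratum_mean: {mean: 130, sd: 2.5}   # or an explicit list
      sigma_between_clusters: {mean: 5, sd: 0.1}
      sigma_between_households: {mean: 7, sd: 0.2}
      sigma_within_household: {mean: 10, sd: 0.2}
      threshold: 140
      seed: 0
    designs:                         # list of DesignSpec sections
      - {name: M1, method: M1, clusters_per_stratum: 100}
      - {name: M2-1000, method: M2, total_clusters: 1000, household_fraction: 1}
      - {method: M2, total_clusters: 3000, household_fraction: 1/3}
    replicates: 1000
    seed: 1

Fractions must be exact: write ``1/3``, not ``0.33``.  Unknown keys are
rejected so that typos fail loudly instead of silently using a default.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import yaml

from .designs import DesignSpec
from .population import ConfigError, GaussianSpec, PopulationConfig

__all__ = ["ScenarioFile", "load_scenario_file", "parse_fraction", "config_hash"]

_POP_KEYS = {
    "n_strata", "stratum_cluster_counts", "cluster_count_bounds",
    "households_per_cluster", "members_per_household", "stratum_mean",
    "sigma_between_clusters", "sigma_between_households",
    "sigma_within_household", "threshold", "seed",
}
_DESIGN_KEYS = {
    "name", "method", "clusters_per_stratum", "interval_rule",
    "total_clusters", "household_fraction", "household_rounding",
}
_TOP_KEYS = {"population", "designs", "replicates", "seed"}


@dataclass(frozen=True)
class ScenarioFile:
    population: PopulationConfig
    designs: tuple[DesignSpec, ...]
    replicates: int
    seed: int
    raw: dict

    @property
    def hash(self) -> str:
        return config_hash(self.raw)


def parse_fraction(value) -> Fraction:
    """Parse an exact rational from an int, exact float, or 'a/b' string."""
    if isinstance(value, str):
        return Fraction(value.strip())
    return Fraction(value)


def config_hash(raw: dict) -> str:
    """Short stable hash of the raw scenario dict, for provenance."""
    canon = json.dumps(raw, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in {where}; "
            f"allowed: {sorted(allowed)}"
        )


def _gaussian(value, where: str) -> GaussianSpec:
    if not isinstance(value, dict) or set(value) != {"mean", "sd"}:
        raise ConfigError(f"{where} must be a mapping with keys mean, sd")
    return GaussianSpec(float(value["mean"]), float(value["sd"]))


def parse_population(section: dict) -> PopulationConfig:
    _check_keys(section, _POP_KEYS, "population")
    kwargs: dict = {}
    for key in ("n_strata", "seed"):
        if key in section:
            kwargs[key] = int(section[key])
    if "threshold" in section:
        kwargs["threshold"] = float(section["threshold"])
    if "stratum_cluster_counts" in section:
        v = section["stratum_cluster_counts"]
        kwargs["stratum_cluster_counts"] = v if isinstance(v, str) else [int(c) for c in v]
    if "cluster_count_bounds" in section:
        lo, hi = section["cluster_count_bounds"]
        kwargs["cluster_count_bounds"] = (int(lo), int(hi))
    if "members_per_household" in section:
        lo, hi = section["members_per_household"]
        kwargs["members_per_household"] = (int(lo), int(hi))
    if "stratum_mean" in section:
        v = section["stratum_mean"]
        kwargs["stratum_mean"] = (
            _gaussian(v, "population.stratum_mean")
            if isinstance(v, dict) else [float(m) for m in v]
        )
    for key in ("households_per_cluster", "sigma_between_clusters",
                "sigma_between_households", "sigma_within_household"):
        if key in section:
            kwargs[key] = _gaussian(section[key], f"population.{key}")
    return PopulationConfig(**kwargs)


def parse_design(section: dict, index: int) -> DesignSpec:
    where = f"designs[{index}]"
    _check_keys(section, _DESIGN_KEYS, where)
    if "method" not in section:
        raise ConfigError(f"{where}: 'method' is required (M1 or M2)")
    kwargs = dict(section)
    if "household_fraction" in kwargs:
        kwargs["household_fraction"] = parse_fraction(kwargs["household_fraction"])
    return DesignSpec(**kwargs)


def load_scenario_file(path) -> ScenarioFile:
    """Parse and validate a scenario YAML file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: scenario file must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top level")
    if "population" not in raw:
        raise ConfigError(f"{path}: missing 'population' section")
    pop = parse_population(raw["population"] or {})
    designs = tuple(
        parse_design(d, i) for i, d in enumerate(raw.get("designs", []))
    )
    names = [d.name for d in designs]
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate design names: {names}")
    replicates = int(raw.get("replicates", 1000))
    if replicates < 1:
        raise ConfigError("replicates must be >= 1")
    return ScenarioFile(
        population=pop,
        designs=designs,
        replicates=replicates,
        seed=int(raw.get("seed", 0)),
        raw=raw,
    )
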