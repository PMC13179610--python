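"""Simulation study harness.

Reproduces the random-graph evaluation protocol at configurable scale: for
every graph-size multiplier ``z``, generate random instances, sample
realizations, run each probing policy over the probe/selection grid

    k in {n_A/4, n_A/2, 3 n_A/4},   l in {k/4, k/2, 3 k/4, k},

and report each achieved value as a fraction of an offline reference.  For
the coverage objective the reference is the LP-relaxation upper bound for
graphs up to ``lp_cutoff_na`` regulators and the offline greedy (Off)
beyond it; for the additive-separable objectives the exact top-l optimum
is used.  Everything is reproducible from a single master seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .algorithms import (
    evaluate_probe_set,
    namp,
    nampcov,
    off,
    offline_ip,
    offline_lp_bound,
    run_policy,
)
from .model import generate_instance, sample_realization
from .objectives import ObjectiveKind, top_l_by_score
from .rng import substream

__all__ = ["ExperimentSpec", "run_grid", "summarize"]

logger = logging.getLogger(__name__)

_GRID_K = (0.25, 0.5, 0.75)
_GRID_L = (0.25, 0.5, 0.75, 1.0)


@dataclass
class ExperimentSpec:
    """Configuration of one simulation experiment."""

    setting: str = "network"
    z_values: tuple[int, ...] = (1, 2, 3)
    k_fractions: tuple[float, ...] = _GRID_K
    l_fractions: tuple[float, ...] = _GRID_L
    n_instances: int = 20
    n_runs_per_instance: int = 5
    objective: str = "cov"
    algorithms: tuple[str, ...] = ("nampcov", "ampcov")
    offline_mode: str = "auto"  # lp | ip | greedy | auto
    lp_cutoff_na: int = 160
    master_seed: int = 0

    def __post_init__(self):
        self.z_values = tuple(int(z) for z in self.z_values)
        self.k_fractions = tuple(float(f) for f in self.k_fractions)
        self.l_fractions = tuple(float(f) for f in self.l_fractions)
        self.algorithms = tuple(self.algorithms)
        self.validate()

    def validate(self) -> None:
        if self.setting not in ("uniform", "network"):
            raise ValueError(f"unknown setting {self.setting!r}")
        if self.offline_mode not in ("lp", "ip", "greedy", "auto"):
            raise ValueError(f"unknown offline mode {self.offline_mode!r}")
        if self.n_instances < 1 or self.n_runs_per_instance < 1:
            raise ValueError("n_instances and n_runs_per_instance must be >= 1")
        if min(self.z_values, default=0) < 1:
            raise ValueError("z values must be >= 1")
        if not all(0 < f <= 1 for f in self.k_fractions + self.l_fractions):
            raise ValueError("grid fractions must lie in (0, 1]")
        ObjectiveKind(self.objective)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentSpec":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "setting": self.setting,
            "z_values": list(self.z_values),
            "k_fractions": list(self.k_fractions),
            "l_fractions": list(self.l_fractions),
            "n_instances": self.n_instances,
            "n_runs_per_instance": self.n_runs_per_instance,
            "objective": self.objective,
            "algorithms": list(self.algorithms),
            "offline_mode": self.offline_mode,
            "lp_cutoff_na": self.lp_cutoff_na,
            "master_seed": self.master_seed,
        }
        Path(path).write_text(yaml.safe_dump(doc))


def _grid_pairs(n_a: int, spec: ExperimentSpec) -> list[tuple[int, int]]:
    pairs = []
    for fk in spec.k_fractions:
        k = max(1, int(np.floor(fk * n_a)))
        for fl in spec.l_fractions:
            l = max(1, int(np.floor(fl * k)))
            pairs.append((k, l))
    return pairs


def _offline_reference(W: np.ndarray, l: int, objective: ObjectiveKind, mode: str) -> float:
    if objective is ObjectiveKind.COV:
        if mode == "lp":
            return offline_lp_bound(W, l)
        if mode == "ip":
            return offline_ip(W, l)
        _, value = off(W, l)
        return value
    realized = W.max(axis=1) if objective is ObjectiveKind.MAX else W.sum(axis=1)
    return float(realized[top_l_by_score(realized, l)].sum())


def run_grid(spec: ExperimentSpec) -> pd.DataFrame:
    """Run the full (z, instance, run, k, l, algorithm) grid.

    Realizations are shared across algorithms within a run, and offline
    references are cached per (realization, l).  Realizations whose offline
    reference is zero are resampled with an incremented sub-seed and the
    event logged (ratios would otherwise be undefined).
    """
    objective = ObjectiveKind(spec.objective)
    records: list[dict] = []
    for z in spec.z_values:
        for inst_idx in range(spec.n_instances):
            inst_rng = substream(spec.master_seed, "instance", spec.setting, z, inst_idx)
            instance = generate_instance(spec.setting, z, inst_rng)
            n_a = instance.n_regulators
            pairs = _grid_pairs(n_a, spec)
            if spec.offline_mode == "auto":
                mode = "lp" if (objective is ObjectiveKind.COV and n_a <= spec.lp_cutoff_na) else "greedy"
            else:
                mode = spec.offline_mode
            if objective is not ObjectiveKind.COV:
                mode = "exact"
            probe_cache: dict = {}
            for run_idx in range(spec.n_runs_per_instance):
                attempt = 0
                while True:
                    run_rng = substream(
                        spec.master_seed, "realization", spec.setting, z, inst_idx, run_idx, attempt
                    )
                    realization = sample_realization(instance, run_rng)
                    W = realization.weights
                    # check every l in the grid has a positive reference
                    offline_cache = {
                        l: _offline_reference(W, l, objective, mode)
                        for l in sorted({l for _, l in pairs})
                    }
                    if min(offline_cache.values()) > 0:
                        break
                    attempt += 1
                    logger.warning(
                        "degenerate realization (offline value 0) at z=%s instance=%s "
                        "run=%s; resampling (attempt %s)", z, inst_idx, run_idx, attempt,
                    )
                    if attempt > 100:
                        raise RuntimeError("could not sample a non-degenerate realization")
                for k, l in pairs:
                    for algorithm in spec.algorithms:
                        t0 = time.perf_counter()
                        if algorithm in ("namp", "nampcov"):
                            # non-adaptive probe sets depend only on (k, l)
                            key = (algorithm, k, l)
                            if key not in probe_cache:
                                if algorithm == "namp":
                                    probe_cache[key] = namp(instance, k, l, objective)
                                else:
                                    probe_cache[key] = nampcov(instance, k, l)
                            run = evaluate_probe_set(probe_cache[key], realization, l, objective)
                        else:
                            run = run_policy(instance, realization, algorithm, k, l, objective)
                        elapsed = time.perf_counter() - t0
                        offline = offline_cache[l]
                        records.append(
                            {
                                "setting": spec.setting,
                                "z": z,
                                "n_A": n_a,
                                "n_B": instance.n_positions,
                                "k": k,
                                "l": l,
                                "algorithm": algorithm,
                                "instance": inst_idx,
                                "run": run_idx,
                                "value": run.value,
                                "offline_value": offline,
                                "offline_mode": mode,
                                "ratio": run.value / offline,
                                "wall_time_s": elapsed,
                            }
                        )
    return pd.DataFrame.from_records(records)


def summarize(
    records: pd.DataFrame,
    group_by: tuple[str, ...] = ("setting", "z", "k", "l", "algorithm"),
) -> pd.DataFrame:
    """Grouped mean/min/max approximation ratio and mean runtime."""
    if records.empty:
        raise ValueError("cannot summarize an empty record table")
    g = records.groupby(list(group_by), as_index=False).agg(
        mean_ratio=("ratio", "mean"),
        min_ratio=("ratio", "min"),
        max_ratio=("ratio", "max"),
        mean_value=("value", "mean"),
        mean_wall_time_s=("wall_time_s", "mean"),
        n_runs=("ratio", "size"),
    )
    return g.sort_values(list(group_by)).reset_index(drop=True)
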