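"""Objective functions for regulator probing and their parent functions.

Three objectives evaluate a selected set ``S`` of regulators on a realized
weight matrix ``W``:

* ``f_cov(S) = sum_b max_{a in S} w_{a,b}`` — weighted maximum coverage:
  every position is credited to the single best selected regulator.
* ``f_max(S) = sum_{a in S} max_b w_{a,b}`` — regulators are independent,
  each contributes its best incident edge.
* ``f_sum(S) = sum_{a in S} sum_b w_{a,b}`` — each contributes all its
  incident weight.

The parent function ``f*(S') = max_{S subset of S', |S| <= l} f(S)`` scores
a probed set by its best feasible sub-selection.  ``f_max``/``f_sum`` admit
an exact top-l solution; for ``f_cov`` the exact parent is NP-hard and is
computed by enumeration only below a subset cap, with the standard
submodular greedy as the scalable mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from math import comb
from typing import Iterable, Mapping

import numpy as np

from .model import ProbingInstance

__all__ = [
    "ObjectiveKind",
    "SelectionProblem",
    "ENUMERATION_CAP",
    "f_cov",
    "f_max",
    "f_sum",
    "objective_function",
    "parent_value",
    "expected_fcov",
]

#: largest number of subsets enumerated by exact parent evaluation
ENUMERATION_CAP = 200_000


class ObjectiveKind(str, Enum):
    COV = "cov"
    MAX = "max"
    SUM = "sum"


@dataclass(frozen=True)
class SelectionProblem:
    """Weight rows available for selection plus the cardinality limit l."""

    rows: Mapping[int, np.ndarray]
    select_limit: int

    def __post_init__(self):
        lengths = {len(v) for v in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("all weight rows must have equal length")
        if self.select_limit < 0:
            raise ValueError("select_limit must be >= 0")

    def matrix(self) -> tuple[list[int], np.ndarray]:
        ids = sorted(self.rows)
        return ids, np.array([self.rows[i] for i in ids], dtype=float)


def _rows(S: Iterable[int], W: np.ndarray) -> np.ndarray:
    idx = list(S)
    W = np.asarray(W, dtype=float)
    if any(not 0 <= a < W.shape[0] for a in idx):
        raise KeyError(f"regulator index outside the available rows: {idx}")
    return W[idx]


def f_cov(S: Iterable[int], W: np.ndarray) -> float:
    rows = _rows(S, W)
    if rows.shape[0] == 0:
        return 0.0
    return float(rows.max(axis=0).sum())


def f_max(S: Iterable[int], W: np.ndarray) -> float:
    rows = _rows(S, W)
    if rows.shape[0] == 0:
        return 0.0
    return float(rows.max(axis=1).sum())


def f_sum(S: Iterable[int], W: np.ndarray) -> float:
    return float(_rows(S, W).sum())


_OBJECTIVES = {
    ObjectiveKind.COV: f_cov,
    ObjectiveKind.MAX: f_max,
    ObjectiveKind.SUM: f_sum,
}


def objective_function(kind: ObjectiveKind | str):
    return _OBJECTIVES[ObjectiveKind(kind)]


def _row_scores(W: np.ndarray, kind: ObjectiveKind) -> np.ndarray:
    if kind is ObjectiveKind.MAX:
        return W.max(axis=1)
    return W.sum(axis=1)


def top_l_by_score(scores: np.ndarray, l: int) -> list[int]:
    """Indices of the l largest scores; ties broken by lowest index."""
    order = np.lexsort((np.arange(scores.size), -scores))
    return sorted(order[: min(l, scores.size)].tolist())


def parent_value(
    rows: Mapping[int, np.ndarray] | np.ndarray,
    l: int,
    kind: ObjectiveKind | str = ObjectiveKind.COV,
    mode: str = "exact",
) -> tuple[float, frozenset[int]]:
    """Best feasible sub-selection of size <= l from the given rows.

    Monotonicity lets the search restrict to subsets of size exactly
    ``min(l, n)``.  For ``max``/``sum`` the exact optimum is the top-l rows
    by row score.  For ``cov``, ``mode='exact'`` enumerates subsets (capped
    at :data:`ENUMERATION_CAP`) and ``mode='greedy'`` runs the submodular
    greedy selector.
    """
    kind = ObjectiveKind(kind)
    if isinstance(rows, Mapping):
        ids = sorted(rows)
        W = np.array([rows[i] for i in ids], dtype=float) if ids else np.empty((0, 0))
    else:
        W = np.asarray(rows, dtype=float)
        ids = list(range(W.shape[0]))
    n = W.shape[0]
    if l <= 0 or n == 0:
        return 0.0, frozenset()
    size = min(l, n)

    if kind in (ObjectiveKind.MAX, ObjectiveKind.SUM):
        picked = top_l_by_score(_row_scores(W, kind), size)
        f = objective_function(kind)
        return f(picked, W), frozenset(ids[i] for i in picked)

    if mode == "greedy":
        from .algorithms import greedy_select

        sel, value = greedy_select(W, size)
        return value, frozenset(ids[i] for i in sel)
    if mode != "exact":
        raise ValueError(f"unknown parent mode {mode!r}")
    if comb(n, size) > ENUMERATION_CAP:
        raise ValueError(
            f"C({n},{size}) exceeds the enumeration cap {ENUMERATION_CAP}; use mode='greedy'"
        )
    best_val, best_set = 0.0, frozenset()
    for subset in combinations(range(n), size):
        val = f_cov(subset, W)
        if val > best_val:
            best_val, best_set = val, frozenset(ids[i] for i in subset)
    return best_val, best_set


def expected_fcov(S: Iterable[int], instance: ProbingInstance) -> float:
    """Exact expected coverage value of a regulator set.

    Under edge independence E[f_cov(S)] = sum_b E[max_{a in S} w_{a,b}],
    with each position's expected max computed from the CDF product.
    """
    idx = sorted(set(S))
    if not idx:
        raise ValueError("expected_fcov of an empty set")
    if instance.deterministic:
        return f_cov(idx, instance.point_weights)
    cdf = instance.cdfs()[idx]  # (|S|, n_B, V+1)
    tail = 1.0 - np.prod(cdf[:, :, :-1], axis=0)
    return float(tail.sum())
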