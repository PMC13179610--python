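"""Probing policies and offline evaluators.

Adaptive policies (``amp``, ``ampcov``) pick each probe using the realized
weights of earlier probes; non-adaptive ones (``namp``, ``nampcov``) fix the
probe set upfront from the edge distributions alone.  After ``k`` probes, at
most ``l`` probed regulators are selected and scored on the realization.

The coverage variants follow the myopic greedy template for monotone
submodular maximization: exact expected marginal gains while the first
``l`` probes are being placed (these are guaranteed to be selectable), and
greedy-estimated gains with expectation-substituted rows afterwards.  The
offline optimum is bracketed by the (1 - 1/e)-greedy from below and the
LP relaxation of the weighted max-coverage integer program from above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .model import ProbingInstance, WeightRealization
from .objectives import ObjectiveKind, objective_function, parent_value, top_l_by_score

__all__ = [
    "ADAPTIVITY_GAP_BOUND",
    "AlgorithmConfig",
    "ProbingRun",
    "greedy_select",
    "brute_force_select",
    "offline_ip",
    "offline_lp_bound",
    "amp",
    "namp",
    "ampcov",
    "nampcov",
    "off",
    "evaluate_probe_set",
    "run_policy",
    "CONVOLUTION_SUPPORT_CAP",
]

#: e / (e - 1): tight adaptivity-gap bound for monotone submodular parent
#: functions (Asadpour & Nazerzadeh).
ADAPTIVITY_GAP_BOUND = math.e / (math.e - 1.0)

#: largest exact row-sum pmf support before amp(sum) switches to a normal
#: approximation of the score variable
CONVOLUTION_SUPPORT_CAP = 10_000

_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class AlgorithmConfig:
    probe_budget: int
    select_limit: int
    objective: ObjectiveKind = ObjectiveKind.COV
    algorithm: str = "nampcov"
    seed: int | None = None

    def validate(self, n_regulators: int) -> None:
        if not 0 <= self.select_limit <= self.probe_budget <= n_regulators:
            raise ValueError(
                f"need l <= k <= n_A, got l={self.select_limit}, "
                f"k={self.probe_budget}, n_A={n_regulators}"
            )


@dataclass(frozen=True)
class ProbingRun:
    """Outcome of one policy execution on one realization."""

    probe_order: tuple[int, ...]
    selected: frozenset[int]
    value: float
    step_gains: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not self.selected <= set(self.probe_order):
            raise ValueError("selected set must be a subset of the probed set")


def _argmax_tiebreak(
    scores: np.ndarray,
    *,
    secondary: np.ndarray | None = None,
    tie_rng: np.random.Generator | None = None,
    tie_rtol: float = _TIE_RTOL,
) -> int:
    """Index of the maximal score.

    Near-ties (within relative tolerance) are resolved by the ``secondary``
    score if given, then by lowest index, or uniformly at random when
    ``tie_rng`` is supplied (used by the triplet-frequency application).
    """
    best = np.nanmax(scores)
    thr = best - abs(best) * tie_rtol - 1e-300
    cands = np.flatnonzero(scores >= thr)
    if secondary is not None and cands.size > 1:
        sec_best = secondary[cands].max()
        sec_thr = sec_best - abs(sec_best) * tie_rtol - 1e-300
        cands = cands[secondary[cands] >= sec_thr]
    if tie_rng is not None and cands.size > 1:
        return int(cands[tie_rng.integers(cands.size)])
    return int(cands[0])


# ---------------------------------------------------------------------------
# Greedy selection and offline evaluators (weighted max coverage)
# ---------------------------------------------------------------------------

def greedy_select(
    W: np.ndarray,
    l: int,
    tie_rng: np.random.Generator | None = None,
    tie_rtol: float = _TIE_RTOL,
) -> tuple[list[int], float]:
    """Submodular greedy for weighted max coverage on realized rows.

    Iteratively adds the row with the largest marginal coverage gain (ties
    to the lowest index, or seeded-random when ``tie_rng`` is given) until
    ``l`` rows are picked or every gain is zero.  Guarantees a
    (1 - 1/e)-fraction of the optimal selection value.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    selected: list[int] = []
    if l <= 0 or n == 0:
        return selected, 0.0
    covered = np.zeros(W.shape[1])
    available = np.ones(n, dtype=bool)
    for _ in range(min(l, n)):
        gains = np.maximum(W - covered, 0.0).sum(axis=1)
        gains[~available] = -np.inf
        a = _argmax_tiebreak(gains, tie_rng=tie_rng, tie_rtol=tie_rtol)
        if gains[a] <= 0:
            break
        selected.append(a)
        available[a] = False
        covered = np.maximum(covered, W[a])
    return selected, float(covered.sum())


def brute_force_select(W: np.ndarray, l: int) -> tuple[list[int], float]:
    """Exact optimum of the coverage selection by subset enumeration."""
    value, sel = parent_value(np.asarray(W, dtype=float), l, ObjectiveKind.COV, mode="exact")
    return sorted(sel), value


def _coverage_program(W: np.ndarray, l: int):
    """Sparse constraint system of the weighted max-coverage program.

    Variables: x_a (select regulator a) followed by y_e for each positive-
    weight edge e = (a, b).  maximize sum w_e y_e subject to
    sum_a x_a <= l, y_e <= x_{a(e)}, and sum_{a} y_{a,b} <= 1 per position.
    """
    W = np.asarray(W, dtype=float)
    n_a, n_b = W.shape
    ea, eb = np.nonzero(W > 0)
    n_e = ea.size
    n_var = n_a + n_e
    c = np.zeros(n_var)
    c[n_a:] = -W[ea, eb]  # linprog/milp minimize

    rows, cols, vals = [], [], []
    # budget row 0: sum x <= l
    rows.extend([0] * n_a)
    cols.extend(range(n_a))
    vals.extend([1.0] * n_a)
    # y_e - x_a <= 0 : rows 1..n_e
    r = np.arange(1, n_e + 1)
    rows.extend(r.tolist())
    cols.extend((n_a + np.arange(n_e)).tolist())
    vals.extend([1.0] * n_e)
    rows.extend(r.tolist())
    cols.extend(ea.tolist())
    vals.extend([-1.0] * n_e)
    # per-position rows
    rows.extend((1 + n_e + eb).tolist())
    cols.extend((n_a + np.arange(n_e)).tolist())
    vals.extend([1.0] * n_e)

    n_rows = 1 + n_e + n_b
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(n_rows, n_var))
    b_ub = np.ones(n_rows)
    b_ub[0] = float(l)
    b_ub[1 : n_e + 1] = 0.0  # y_e - x_a <= 0
    return c, A, b_ub, n_a, n_e


def offline_ip(W: np.ndarray, l: int) -> float:
    """Optimal offline coverage value via the max-coverage integer program."""
    if l < 1:
        raise ValueError("l must be >= 1")
    c, A, b_ub, n_a, n_e = _coverage_program(W, l)
    if n_e == 0:
        return 0.0
    integrality = np.zeros(n_a + n_e)
    integrality[:n_a] = 1  # x binary; y integral automatically at optimum
    res = milp(
        c=c,
        constraints=LinearConstraint(A, -np.inf, b_ub),
        integrality=integrality,
        bounds=Bounds(0, 1),
    )
    if not res.success:
        raise RuntimeError(f"IP solver failed: {res.message}")
    return float(-res.fun)


def offline_lp_bound(W: np.ndarray, l: int) -> float:
    """LP-relaxation upper bound on the optimal offline coverage value.

    Solves the relaxation of the max-coverage program in its equivalent
    layered form: per position the fractional-knapsack value of capacities
    ``x`` equals the sum over weight levels of ``min(1, sum_{w >= level} x_a)``,
    so one bounded variable per (position, distinct weight level) replaces
    the per-edge ``y`` variables.  The optimal value is identical to the
    edge-variable relaxation (maximize sum w_e y_e, y_e <= x_a,
    sum_a y_{a,b} <= 1) and the solve is much smaller.
    """
    if l < 1:
        raise ValueError("l must be >= 1")
    W = np.asarray(W, dtype=float)
    n_a, n_b = W.shape
    if not np.any(W > 0):
        return 0.0

    rows_list: list[np.ndarray] = []
    cols_list: list[np.ndarray] = []
    heights: list[np.ndarray] = []
    n_layer = 0
    integral = np.allclose(W, np.round(W))
    if integral:
        Wi = np.round(W).astype(int)
        for v in range(1, int(Wi.max()) + 1):
            mask = Wi >= v  # (n_A, n_B)
            active = np.flatnonzero(mask.any(axis=0))
            if active.size == 0:
                continue
            a_idx, b_idx = np.nonzero(mask[:, active])
            rows_list.append(1 + n_layer + b_idx)
            cols_list.append(a_idx)
            heights.append(np.ones(active.size))
            n_layer += active.size
    else:
        r_acc: list[int] = []
        c_acc: list[int] = []
        h_acc: list[float] = []
        for b in range(n_b):
            col = W[:, b]
            prev = 0.0
            for v in np.unique(col[col > 0]):
                members = np.flatnonzero(col >= v)
                r_acc.extend([1 + n_layer] * members.size)
                c_acc.extend(members.tolist())
                h_acc.append(float(v - prev))
                prev = float(v)
                n_layer += 1
        rows_list.append(np.asarray(r_acc, dtype=int))
        cols_list.append(np.asarray(c_acc, dtype=int))
        heights.append(np.asarray(h_acc))

    rows = np.concatenate(rows_list)
    cols = np.concatenate(cols_list)
    # each layer row: t_layer - sum_{a: w >= level} x_a <= 0
    layer_rows = np.concatenate([rows, 1 + np.arange(n_layer), np.zeros(n_a, dtype=int)])
    layer_cols = np.concatenate([cols, n_a + np.arange(n_layer), np.arange(n_a)])
    layer_vals = np.concatenate([-np.ones(rows.size), np.ones(n_layer), np.ones(n_a)])

    n_var = n_a + n_layer
    A = sparse.csr_matrix((layer_vals, (layer_rows, layer_cols)), shape=(1 + n_layer, n_var))
    b_ub = np.zeros(1 + n_layer)
    b_ub[0] = float(l)  # budget row: sum x <= l
    c = np.zeros(n_var)
    c[n_a:] = -np.concatenate(heights)
    res = linprog(c, A_ub=A, b_ub=b_ub, bounds=(0, 1), method="highs-ipm")
    if not res.success:
        raise RuntimeError(f"LP solver failed: {res.message}")
    return float(-res.fun)


def off(
    realization: WeightRealization | np.ndarray,
    l: int,
    tie_rng: np.random.Generator | None = None,
) -> tuple[list[int], float]:
    """Greedy approximation of the optimal offline selection (Off)."""
    W = realization.weights if isinstance(realization, WeightRealization) else realization
    return greedy_select(W, l, tie_rng=tie_rng)


# ---------------------------------------------------------------------------
# Scalar score reductions for the additive-separable objectives
# ---------------------------------------------------------------------------

def _row_score_pmfs(instance: ProbingInstance, kind: ObjectiveKind):
    """Reduce each regulator to the distribution of its scalar score.

    ``sum``: iterated convolution of the row's edge pmfs (exact) up to
    :data:`CONVOLUTION_SUPPORT_CAP`, then a normal approximation.
    ``max``: exact pmf from the product of edge CDFs.
    Returns a list of ``('pmf', vector)`` or ``('normal', mu, sigma)`` and a
    vector of expected scores.
    """
    n_a, n_b = instance.n_regulators, instance.n_positions
    vmax = instance.pmfs.shape[2] - 1
    out = []
    means = np.zeros(n_a)
    pmfs = instance.pmfs
    values = np.arange(vmax + 1, dtype=float)
    if kind is ObjectiveKind.MAX:
        cdf = np.cumsum(pmfs, axis=2)
        prod = np.prod(cdf, axis=1)  # P(max <= v), (n_A, V+1)
        score_pmf = np.diff(np.concatenate([np.zeros((n_a, 1)), prod], axis=1))
        for a in range(n_a):
            p = np.clip(score_pmf[a], 0, None)
            p /= p.sum()
            out.append(("pmf", p))
            means[a] = values @ p
        return out, means
    if kind is not ObjectiveKind.SUM:
        raise ValueError("scalar reduction defined for max/sum objectives only")
    full_support = n_b * vmax + 1
    mu = pmfs @ values  # (n_A, n_B) per-edge means
    var = pmfs @ (values**2) - mu**2
    if full_support <= CONVOLUTION_SUPPORT_CAP:
        for a in range(n_a):
            acc = np.ones(1)
            for b in range(n_b):
                acc = np.convolve(acc, pmfs[a, b])
            acc = np.clip(acc, 0, None)
            acc /= acc.sum()
            out.append(("pmf", acc))
            means[a] = np.arange(acc.size) @ acc
        return out, means
    for a in range(n_a):
        m, s = float(mu[a].sum()), float(np.sqrt(var[a].sum()))
        out.append(("normal", m, s))
        means[a] = m
    return out, means


def _expected_excess(score, t: float) -> float:
    """E[(X - t)+] for a scalar score distribution."""
    if score[0] == "pmf":
        p = score[1]
        v = np.arange(p.size, dtype=float)
        return float(np.maximum(v - t, 0.0) @ p)
    _, m, s = score
    if s <= 0:
        return max(m - t, 0.0)
    z = (m - t) / s
    return float((m - t) * stats.norm.cdf(z) + s * stats.norm.pdf(z))


# ---------------------------------------------------------------------------
# Policies for f_max / f_sum
# ---------------------------------------------------------------------------

def amp(
    instance: ProbingInstance,
    realization: WeightRealization,
    k: int,
    l: int,
    kind: ObjectiveKind | str,
) -> ProbingRun:
    """Adaptive myopic policy for the additive-separable objectives.

    Each regulator is reduced to a scalar random score; at every step the
    policy probes the regulator maximizing the expected marginal increase
    E[(X_a - t)+], where t is the current l-th best realized score among
    probes (0 while fewer than l are probed).  Near-ties are resolved by
    expected score, so on deterministic instances the probe order is by
    descending score.
    """
    kind = ObjectiveKind(kind)
    if kind is ObjectiveKind.COV:
        raise ValueError("amp handles max/sum; use ampcov for coverage")
    AlgorithmConfig(k, l, kind, "amp").validate(instance.n_regulators)
    scores, means = _row_score_pmfs(instance, kind)
    W = realization.weights
    realized = W.max(axis=1) if kind is ObjectiveKind.MAX else W.sum(axis=1)

    probed: list[int] = []
    gains_log: list[float] = []
    available = np.ones(instance.n_regulators, dtype=bool)
    for _ in range(k):
        if len(probed) >= l and l > 0:
            t = float(np.sort(realized[probed])[::-1][l - 1])
        else:
            t = 0.0
        exp_gain = np.full(instance.n_regulators, -np.inf)
        for a in np.flatnonzero(available):
            exp_gain[a] = _expected_excess(scores[a], t)
        a = _argmax_tiebreak(exp_gain, secondary=means)
        probed.append(a)
        gains_log.append(float(exp_gain[a]))
        available[a] = False

    picked = [probed[i] for i in top_l_by_score(realized[probed], l)]
    value = objective_function(kind)(picked, W)
    return ProbingRun(tuple(probed), frozenset(picked), value, tuple(gains_log))


def namp(instance: ProbingInstance, k: int, l: int, kind: ObjectiveKind | str) -> list[int]:
    """Non-adaptive probe set: top-k regulators by expected row score.

    ``sum`` ranks by expected sum of incident edge weights; ``max`` by the
    exact expected row maximum.  Ties go to the lowest index.
    """
    kind = ObjectiveKind(kind)
    if kind is ObjectiveKind.COV:
        raise ValueError("namp handles max/sum; use nampcov for coverage")
    AlgorithmConfig(k, l, kind, "namp").validate(instance.n_regulators)
    if kind is ObjectiveKind.SUM:
        scores = instance.expected().sum(axis=1)
    else:
        if instance.deterministic:
            scores = instance.point_weights.max(axis=1)
        else:
            cdf = instance.cdfs()
            prod = np.prod(cdf[:, :, :-1], axis=1)  # (n_A, V)
            scores = (1.0 - prod).sum(axis=1)
    return top_l_by_score(scores, k)


# ---------------------------------------------------------------------------
# Policies for f_cov
# ---------------------------------------------------------------------------

def _exact_cov_gains(
    instance: ProbingInstance, covered: np.ndarray, available: np.ndarray
) -> np.ndarray:
    """Exact expected coverage gain sum_b E[(w_{a,b} - m_b)+] per candidate."""
    gains = np.full(instance.n_regulators, -np.inf)
    if instance.deterministic:
        g = np.maximum(instance.point_weights - covered, 0.0).sum(axis=1)
    else:
        pmfs = instance.pmfs
        values = np.arange(pmfs.shape[2], dtype=float)
        relu = np.maximum(values[None, :] - covered[:, None], 0.0)  # (n_B, V+1)
        g = np.einsum("abv,bv->a", pmfs, relu)
    gains[available] = g[available]
    return gains


def ampcov(
    instance: ProbingInstance,
    realization: WeightRealization,
    k: int,
    l: int,
    tie_rng: np.random.Generator | None = None,
    tie_rtol: float = _TIE_RTOL,
) -> ProbingRun:
    """Adaptive myopic coverage policy (AmpCov).

    First ``l`` probes maximize the exact expected coverage gain against the
    realized cover of earlier probes (every early probe is selectable, so
    the marginal is exact).  Later probes substitute each candidate row by
    its expected values and score it by the greedy selection value of the
    probed rows plus the substituted row, minus the greedy value of the
    probed rows alone.  The final selection is greedy on the k realized rows.
    """
    AlgorithmConfig(k, l, ObjectiveKind.COV, "ampcov").validate(instance.n_regulators)
    n_a = instance.n_regulators
    W = realization.weights
    expected = instance.expected()
    probed: list[int] = []
    gains_log: list[float] = []
    available = np.ones(n_a, dtype=bool)
    covered = np.zeros(instance.n_positions)

    for _ in range(min(l, k)):
        gains = _exact_cov_gains(instance, covered, available)
        a = _argmax_tiebreak(gains, tie_rng=tie_rng, tie_rtol=tie_rtol)
        probed.append(a)
        gains_log.append(float(gains[a]))
        available[a] = False
        covered = np.maximum(covered, W[a])

    while len(probed) < k:
        base_rows = W[probed]
        _, base_val = greedy_select(base_rows, l)
        gains = np.full(n_a, -np.inf)
        for a in np.flatnonzero(available):
            rows = np.vstack([base_rows, expected[a]])
            _, val = greedy_select(rows, l)
            gains[a] = val - base_val
        a = _argmax_tiebreak(gains, tie_rng=tie_rng, tie_rtol=tie_rtol)
        probed.append(a)
        gains_log.append(float(gains[a]))
        available[a] = False

    sel_pos, value = greedy_select(W[probed], l, tie_rng=tie_rng, tie_rtol=tie_rtol)
    selected = frozenset(probed[i] for i in sel_pos)
    return ProbingRun(tuple(probed), selected, value, tuple(gains_log))


def nampcov(
    instance: ProbingInstance,
    k: int,
    l: int,
    tie_rng: np.random.Generator | None = None,
    tie_rtol: float = _TIE_RTOL,
) -> list[int]:
    """Non-adaptive coverage probe set (NampCov).

    The first ``l`` picks greedily maximize the exact increment of the
    expected coverage value of the growing prefix (per-position expected
    max via CDF products); the remaining ``k - l`` picks are the unchosen
    regulators with the highest expected row sums.
    """
    AlgorithmConfig(k, l, ObjectiveKind.COV, "nampcov").validate(instance.n_regulators)
    n_a, n_b = instance.n_regulators, instance.n_positions
    chosen: list[int] = []
    available = np.ones(n_a, dtype=bool)

    if instance.deterministic:
        Wdet = instance.point_weights
        covered = np.zeros(n_b)
        for _ in range(min(l, k)):
            gains = np.full(n_a, -np.inf)
            gains[available] = np.maximum(Wdet - covered, 0.0).sum(axis=1)[available]
            a = _argmax_tiebreak(gains, tie_rng=tie_rng, tie_rtol=tie_rtol)
            chosen.append(a)
            available[a] = False
            covered = np.maximum(covered, Wdet[a])
    else:
        cdf = instance.cdfs()
        G = np.ones((n_b, cdf.shape[2] - 1))  # prefix CDF product at v = 0..V-1
        tail = 1.0 - cdf[:, :, :-1]
        for _ in range(min(l, k)):
            gains = np.full(n_a, -np.inf)
            gains[available] = np.einsum("abv,bv->a", tail, G)[available]
            a = _argmax_tiebreak(gains, tie_rng=tie_rng, tie_rtol=tie_rtol)
            chosen.append(a)
            available[a] = False
            G *= cdf[a, :, :-1]

    if len(chosen) < k:
        row_sums = instance.expected().sum(axis=1)
        remaining = np.flatnonzero(available)
        if tie_rng is not None:
            # randomized tie handling among near-equal expected sums
            while len(chosen) < k:
                scores = np.full(n_a, -np.inf)
                scores[available] = row_sums[available]
                a = _argmax_tiebreak(scores, tie_rng=tie_rng, tie_rtol=tie_rtol)
                chosen.append(a)
                available[a] = False
        else:
            order = remaining[np.lexsort((remaining, -row_sums[remaining]))]
            chosen.extend(order[: k - len(chosen)].tolist())
    return chosen


def evaluate_probe_set(
    probe_set: list[int],
    realization: WeightRealization,
    l: int,
    objective: ObjectiveKind | str = ObjectiveKind.COV,
    tie_rng: np.random.Generator | None = None,
    tie_rtol: float = _TIE_RTOL,
) -> ProbingRun:
    """Select and score the best feasible subset of a fixed probe set."""
    objective = ObjectiveKind(objective)
    W = realization.weights
    rows = W[probe_set]
    if objective is ObjectiveKind.COV:
        sel_pos, value = greedy_select(rows, l, tie_rng=tie_rng, tie_rtol=tie_rtol)
    else:
        realized = rows.max(axis=1) if objective is ObjectiveKind.MAX else rows.sum(axis=1)
        sel_pos = top_l_by_score(realized, l)
        value = objective_function(objective)([probe_set[i] for i in sel_pos], W)
    selected = frozenset(probe_set[i] for i in sel_pos)
    return ProbingRun(tuple(probe_set), selected, float(value))


def run_policy(
    instance: ProbingInstance,
    realization: WeightRealization,
    algorithm: str,
    k: int,
    l: int,
    objective: ObjectiveKind | str = ObjectiveKind.COV,
    tie_rng: np.random.Generator | None = None,
    tie_rtol: float = _TIE_RTOL,
) -> ProbingRun:
    """Execute a policy end to end and score its selection on the realization."""
    objective = ObjectiveKind(objective)
    if algorithm == "amp":
        return amp(instance, realization, k, l, objective)
    if algorithm == "ampcov":
        return ampcov(instance, realization, k, l, tie_rng=tie_rng, tie_rtol=tie_rtol)
    if algorithm in ("namp", "nampcov"):
        if algorithm == "namp":
            probe_set = namp(instance, k, l, objective)
        else:
            probe_set = nampcov(instance, k, l, tie_rng=tie_rng, tie_rtol=tie_rtol)
        return evaluate_probe_set(probe_set, realization, l, objective, tie_rng, tie_rtol)
    if algorithm == "off":
        W = realization.weights
        if objective is ObjectiveKind.COV:
            sel, value = off(W, l, tie_rng=tie_rng)
        else:
            realized = W.max(axis=1) if objective is ObjectiveKind.MAX else W.sum(axis=1)
            sel = top_l_by_score(realized, l)
            value = objective_function(objective)(sel, W)
        return ProbingRun(tuple(range(instance.n_regulators)), frozenset(sel), float(value))
    raise ValueError(f"unknown algorithm {algorithm!r}")
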