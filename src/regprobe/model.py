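"""Random bipartite graph model for regulator probing.

A complete bipartite graph connects ``n_A`` regulators (transcription
factors) to ``n_B`` positions (genes).  Each edge carries a discrete weight
distribution over the value set ``{0, ..., V_max}``; probing a regulator
reveals the realized weights of all its incident edges.  Two simulation
regimes are provided:

* ``uniform`` — square graphs (``n_A = n_B = 16 z``) whose edge pmfs are
  independently drawn random normalized weight vectors over ``16 z`` values.
* ``network`` — gene-regulatory-like graphs (``n_A = 16 z``,
  ``n_B = 400 z``) with 10 weight values and per-edge truncated Poisson
  distributions whose rates are drawn uniformly from [0.5, 2.5].

Deterministic instances (every edge a point mass) additionally accept
arbitrary non-negative real weights, so that networks built from fractional
regulatory-activity scores can be probed directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "EdgeDistribution",
    "ProbingInstance",
    "WeightRealization",
    "ProbeState",
    "uniform_random_distribution",
    "truncated_poisson_distribution",
    "generate_instance",
    "sample_realization",
    "expected_value",
    "expected_max",
]

_MASS_TOL = 1e-9


class EdgeDistribution:
    """Discrete pmf of a single edge weight over ``{0, ..., support_max}``."""

    __slots__ = ("pmf",)

    def __init__(self, pmf: Sequence[float] | np.ndarray):
        arr = np.asarray(pmf, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("pmf must be a non-empty 1-d vector")
        if np.any(arr < -_MASS_TOL):
            raise ValueError("pmf entries must be non-negative")
        total = float(arr.sum())
        if abs(total - 1.0) > _MASS_TOL:
            raise ValueError(f"pmf must sum to 1 (got {total!r})")
        self.pmf = np.clip(arr, 0.0, None)

    @property
    def support_max(self) -> int:
        return self.pmf.size - 1

    @property
    def values(self) -> np.ndarray:
        return np.arange(self.pmf.size)

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.pmf)

    @property
    def is_point_mass(self) -> bool:
        return bool(np.isclose(self.pmf, 1.0, atol=_MASS_TOL).any())

    @property
    def point_value(self) -> int:
        if not self.is_point_mass:
            raise ValueError("distribution is not a point mass")
        return int(np.argmax(self.pmf))

    def expected_value(self) -> float:
        return float(self.values @ self.pmf)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, EdgeDistribution) and np.array_equal(self.pmf, other.pmf)

    def __repr__(self) -> str:
        return f"EdgeDistribution(support_max={self.support_max})"

    @classmethod
    def point_mass(cls, value: int, support_max: int) -> "EdgeDistribution":
        if not 0 <= value <= support_max:
            raise ValueError("point-mass value outside support")
        pmf = np.zeros(support_max + 1)
        pmf[value] = 1.0
        return cls(pmf)


def uniform_random_distribution(support_max: int, rng: np.random.Generator) -> EdgeDistribution:
    """Random normalized weight vector over ``{0, ..., support_max}``.

    One independent uniform[0, 1] weight is drawn per value in the support
    and the vector is normalized to sum to one.
    """
    if support_max < 0:
        raise ValueError("support_max must be >= 0")
    raw = rng.random(support_max + 1)
    return EdgeDistribution(raw / raw.sum())


def truncated_poisson_distribution(rate: float, support_max: int) -> EdgeDistribution:
    """Poisson(rate) pmf with tail mass ``P(X >= support_max)`` lumped at the cap."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    if support_max < 1:
        raise ValueError("support_max must be >= 1")
    pmf = stats.poisson.pmf(np.arange(support_max + 1), rate)
    pmf[support_max] = stats.poisson.sf(support_max - 1, rate)
    return EdgeDistribution(pmf)


class ProbingInstance:
    """Complete bipartite probing instance.

    Backed either by a pmf grid of shape ``(n_A, n_B, V_max + 1)``
    (stochastic, integer support) or by a non-negative real weight matrix
    (deterministic point masses, e.g. a loaded TF-gene network).
    """

    def __init__(
        self,
        *,
        pmfs: np.ndarray | None = None,
        weights: np.ndarray | None = None,
        setting: str | None = None,
        seed: int | None = None,
    ):
        if (pmfs is None) == (weights is None):
            raise ValueError("provide exactly one of pmfs or weights")
        self.setting = setting
        self.seed = seed
        if pmfs is not None:
            pmfs = np.asarray(pmfs, dtype=float)
            if pmfs.ndim != 3:
                raise ValueError("pmfs must have shape (n_A, n_B, V_max + 1)")
            sums = pmfs.sum(axis=2)
            if np.any(pmfs < -_MASS_TOL) or np.any(np.abs(sums - 1.0) > 1e-8):
                raise ValueError("every edge pmf must be non-negative and sum to 1")
            self._pmfs: np.ndarray | None = pmfs
            self._weights: np.ndarray | None = None
        else:
            weights = np.asarray(weights, dtype=float)
            if weights.ndim != 2:
                raise ValueError("weights must be a 2-d matrix")
            if np.any(weights < 0):
                raise ValueError("weights must be non-negative")
            self._pmfs = None
            self._weights = weights

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_pmfs(cls, pmfs: np.ndarray, **kw) -> "ProbingInstance":
        return cls(pmfs=pmfs, **kw)

    @classmethod
    def from_distributions(
        cls, grid: Sequence[Sequence[EdgeDistribution]], **kw
    ) -> "ProbingInstance":
        pmfs = np.array([[d.pmf for d in row] for row in grid], dtype=float)
        return cls(pmfs=pmfs, **kw)

    @classmethod
    def from_weights(cls, weights: np.ndarray, **kw) -> "ProbingInstance":
        """Deterministic instance with arbitrary non-negative real weights."""
        return cls(weights=weights, **kw)

    # -- basic geometry ---------------------------------------------------
    @property
    def n_regulators(self) -> int:
        g = self._pmfs if self._pmfs is not None else self._weights
        return g.shape[0]

    @property
    def n_positions(self) -> int:
        g = self._pmfs if self._pmfs is not None else self._weights
        return g.shape[1]

    @property
    def support_max(self) -> int | None:
        """Largest value of the integer support; None for real-valued instances."""
        if self._pmfs is not None:
            return self._pmfs.shape[2] - 1
        w = self._weights
        if np.allclose(w, np.round(w)):
            return int(np.round(w.max())) if w.size else 0
        return None

    @property
    def deterministic(self) -> bool:
        if self._weights is not None:
            return True
        return bool(np.isclose(self._pmfs, 1.0, atol=_MASS_TOL).any(axis=2).all())

    # -- dense views ------------------------------------------------------
    @property
    def pmfs(self) -> np.ndarray:
        """Pmf grid (n_A, n_B, V_max + 1); built on the fly for integer-valued
        deterministic instances."""
        if self._pmfs is not None:
            return self._pmfs
        vmax = self.support_max
        if vmax is None:
            raise ValueError("real-valued deterministic instance has no integer pmf grid")
        grid = np.zeros((self.n_regulators, self.n_positions, vmax + 1))
        idx = np.round(self._weights).astype(int)
        a, b = np.indices(idx.shape)
        grid[a, b, idx] = 1.0
        return grid

    def cdfs(self) -> np.ndarray:
        return np.cumsum(self.pmfs, axis=2)

    def expected(self) -> np.ndarray:
        """Matrix of per-edge expected weights."""
        if self._weights is not None:
            return self._weights
        values = np.arange(self._pmfs.shape[2], dtype=float)
        return self._pmfs @ values

    @property
    def point_weights(self) -> np.ndarray:
        """Realized matrix of a deterministic instance."""
        if not self.deterministic:
            raise ValueError("instance is not deterministic")
        if self._weights is not None:
            return self._weights
        return np.argmax(self._pmfs, axis=2).astype(float)

    def distribution(self, regulator: int, position: int) -> EdgeDistribution:
        if self._pmfs is not None:
            return EdgeDistribution(self._pmfs[regulator, position])
        vmax = self.support_max
        if vmax is None:
            raise ValueError("real-valued weights have no integer-support distribution")
        return EdgeDistribution.point_mass(int(self._weights[regulator, position]), vmax)

    def row_distributions(self, regulator: int) -> list[EdgeDistribution]:
        return [self.distribution(regulator, b) for b in range(self.n_positions)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProbingInstance):
            return NotImplemented
        if (self._pmfs is None) != (other._pmfs is None):
            return False
        if self._pmfs is not None:
            return np.array_equal(self._pmfs, other._pmfs)
        return np.array_equal(self._weights, other._weights)

    def __repr__(self) -> str:
        kind = "deterministic" if self.deterministic else "stochastic"
        return (
            f"ProbingInstance({kind}, n_A={self.n_regulators}, "
            f"n_B={self.n_positions}, V_max={self.support_max})"
        )


def generate_instance(setting: str, z: int, rng: np.random.Generator) -> ProbingInstance:
    """Generate one random instance of the given simulation regime.

    ``uniform``: n_A = n_B = 16 z, value set of size 16 z, random normalized
    pmfs.  ``network``: n_A = 16 z, n_B = 400 z, value set of size 10,
    truncated Poisson edges with rates drawn uniformly from [0.5, 2.5].
    """
    if z < 1:
        raise ValueError("z must be >= 1")
    if setting == "uniform":
        n_a = n_b = 16 * z
        n_values = 16 * z
        raw = rng.random((n_a, n_b, n_values))
        pmfs = raw / raw.sum(axis=2, keepdims=True)
    elif setting == "network":
        n_a, n_b = 16 * z, 400 * z
        vmax = 9
        lam = rng.uniform(0.5, 2.5, size=(n_a, n_b))
        values = np.arange(vmax + 1)
        pmfs = stats.poisson.pmf(values[None, None, :], lam[:, :, None])
        pmfs[:, :, vmax] = stats.poisson.sf(vmax - 1, lam)
    else:
        raise ValueError(f"unknown setting {setting!r}")
    return ProbingInstance(pmfs=pmfs, setting=setting)


@dataclass(frozen=True)
class WeightRealization:
    """A drawn weight matrix for one instance."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or np.any(w < 0):
            raise ValueError("realization must be a non-negative 2-d matrix")
        object.__setattr__(self, "weights", w)

    def row(self, regulator: int) -> np.ndarray:
        return self.weights[regulator]


def sample_realization(instance: ProbingInstance, rng: np.random.Generator) -> WeightRealization:
    """Draw every edge weight independently from its distribution.

    Deterministic instances return their point-mass values unchanged.
    """
    if instance.deterministic:
        return WeightRealization(instance.point_weights.copy())
    cdf = instance.cdfs()
    u = rng.random((instance.n_regulators, instance.n_positions))
    weights = (cdf < u[:, :, None]).sum(axis=2).astype(float)
    return WeightRealization(weights)


@dataclass(frozen=True)
class ProbeState:
    """Partial view of a realization after probing a set of regulators."""

    instance: ProbingInstance
    realization: WeightRealization
    probed: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self):
        n_a = self.instance.n_regulators
        if len(set(self.probed)) != len(self.probed):
            raise ValueError("probed regulators must be distinct")
        if any(not 0 <= a < n_a for a in self.probed):
            raise ValueError("probed regulator index out of range")

    def probe(self, regulator: int) -> "ProbeState":
        if regulator in self.probed:
            raise ValueError(f"regulator {regulator} already probed")
        return ProbeState(self.instance, self.realization, self.probed + (regulator,))

    def observed_row(self, regulator: int) -> np.ndarray:
        if regulator not in self.probed:
            raise ValueError(f"regulator {regulator} has not been probed")
        return self.realization.row(regulator)

    def observed_rows(self) -> np.ndarray:
        """Realized rows of the probed regulators, in probe order."""
        if not self.probed:
            return np.empty((0, self.instance.n_positions))
        return self.realization.weights[list(self.probed)]


def expected_value(dist: EdgeDistribution) -> float:
    return dist.expected_value()


def expected_max(dists: Iterable[EdgeDistribution]) -> float:
    """Exact E[max] of independent non-negative integer variables.

    Uses the tail identity E[max] = sum_{v>=1} P(max >= v)
    = sum_{v=1}^{V} (1 - prod_i F_i(v - 1)).
    """
    dists = list(dists)
    if not dists:
        raise ValueError("expected_max of an empty list")
    vmax = dists[0].support_max
    if any(d.support_max != vmax for d in dists):
        raise ValueError("distributions must share a common support")
    cdf = np.array([d.cdf() for d in dists])
    # product of CDFs at v-1 for v = 1..V_max
    return float((1.0 - np.prod(cdf[:, :-1], axis=0)).sum())
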