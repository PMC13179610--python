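"""Worked examples and synthetic data generators.

Every fixture ships with a recomputation path for its ground truth: the
4x4 counterexample instance carries its exhaustively enumerable parent
values, and the synthetic regulatory fixture carries an exact-rational
hypergeometric oracle predicting which edges survive enrichment gating,
plus the brute-force optimal triplet.

The synthetic regulatory fixture emulates the input tables of a TF-gene
network build (RE-gene links, binarized RE-motif hits, a TF expression
matrix) with planted TF->gene modules: each planted TF saturates the REs
of its own block of module genes, so the planted TF set is the coverage
optimum, and planted TFs share a latent expression factor so their
pairwise correlation has the closed form 1 / (1 + sigma^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ProbingInstance
from .network import REGeneLinks, REMotifHits
from .rng import substream

__all__ = [
    "CounterexampleFixture",
    "counterexample_fixture",
    "FixtureBundle",
    "synth_regulatory_fixture",
    "exact_fisher_greater",
]


# ---------------------------------------------------------------------------
# The 4x4 counterexample instance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CounterexampleFixture:
    """Deterministic 4x4 instance witnessing non-submodular parent coverage.

    With l = 2, the parent coverage values of the nested probed sets are
    {1,2} -> 2, {1,2,3} -> 2, {1,2,4} -> 3, {1,2,3,4} -> 4, so the marginal
    of regulator 4 grows (2 > 1) as the base set grows.
    """

    instance: ProbingInstance
    k: int
    l: int
    #: exact parent coverage values keyed by 1-based regulator sets
    parent_values: dict[frozenset[int], float]

    @property
    def weights(self) -> np.ndarray:
        return self.instance.point_weights


def counterexample_fixture() -> CounterexampleFixture:
    weights = np.array(
        [
            [1, 0, 0, 0],
            [0, 1, 0, 0],
            [0, 0, 1, 0],
            [1, 1, 0, 1],
        ],
        dtype=float,
    )
    instance = ProbingInstance.from_weights(weights)
    parent = {
        frozenset({1, 2}): 2.0,
        frozenset({1, 2, 3}): 2.0,
        frozenset({1, 2, 4}): 3.0,
        frozenset({1, 2, 3, 4}): 4.0,
    }
    return CounterexampleFixture(instance, k=4, l=2, parent_values=parent)


# ---------------------------------------------------------------------------
# Exact rational Fisher oracle
# ---------------------------------------------------------------------------

def exact_fisher_greater(a: int, b: int, c: int, d: int) -> Fraction:
    """One-sided (greater) Fisher exact p as an exact rational.

    Direct hypergeometric upper-tail summation: with N = a+b+c+d REs of
    which K = a+c carry the TFBS, and n = a+b linked to the gene,
    p = sum_{j >= a} C(K, j) C(N-K, n-j) / C(N, n).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    N, K, n = a + b + c + d, a + c, a + b
    numerator = sum(
        comb(K, j) * comb(N - K, n - j) for j in range(a, min(K, n) + 1)
    )
    return Fraction(numerator, comb(N, n))


# ---------------------------------------------------------------------------
# Synthetic regulatory fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureBundle:
    """Synthetic input tables plus oracle-recomputed ground truth.

    ``expected_edges`` are the (tf, gene, weight) triples predicted to
    survive enrichment gating at ``alpha`` by the exact rational oracle.
    The files written by the ``write_*`` helpers are labelled synthetic
    stand-ins for real RE-based inputs.
    """

    name: str
    links: REGeneLinks
    hits: REMotifHits
    expression: pd.DataFrame  # TFs x samples
    planted_triplet: tuple[str, ...]
    planted_genes: tuple[str, ...]
    expected_edges: tuple[tuple[str, str, float], ...]
    alpha: float
    noise_sd: float

    @property
    def expected_pairwise_r(self) -> float:
        """Closed-form correlation of two planted TFs sharing a unit factor."""
        return 1.0 / (1.0 + self.noise_sd**2)

    def write_links_tsv(self, path: str | Path) -> None:
        rows = [
            {"re_id": re, "gene_id": gene}
            for gene in sorted(self.links.links)
            for re in sorted(self.links.links[gene])
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def write_hits_tsv(self, path: str | Path) -> None:
        rows = [
            {"re_id": re, "tf_id": tf}
            for tf in sorted(self.hits.hits)
            for re in sorted(self.hits.hits[tf])
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def write_expression_csv(self, path: str | Path) -> None:
        self.expression.to_csv(path)


def synth_regulatory_fixture(
    n_genes: int = 24,
    n_tfs: int = 12,
    res_per_gene: int = 6,
    n_module_genes: int = 12,
    n_module_tfs: int = 3,
    within_density: float = 1.0,
    background_density: float = 0.02,
    n_samples: int = 40,
    noise_sd: float = 0.5,
    alpha: float = 0.05,
    seed: int = 0,
) -> FixtureBundle:
    """Generate a synthetic RE/TF/gene bundle with a planted optimal triplet.

    Each gene owns ``res_per_gene`` private REs.  The first
    ``n_module_genes`` genes are partitioned round-robin among the first
    ``n_module_tfs`` TFs; a planted TF hits a ``within_density`` fraction
    of the REs of its block genes.  All TFs additionally hit background REs
    independently with probability ``background_density``.  Planted TFs
    share a standard-normal latent expression factor with additive noise of
    standard deviation ``noise_sd``; background TFs are independent noise.
    """
    if not 0 <= background_density <= 1 or not 0 <= within_density <= 1:
        raise ValueError("densities must lie in [0, 1]")
    if n_module_tfs > n_tfs or n_module_genes > n_genes:
        raise ValueError("planted module larger than the fixture")
    if n_module_tfs > 0 and n_module_genes < n_module_tfs:
        raise ValueError("need at least one module gene per planted TF")

    genes = [f"G{i:03d}" for i in range(n_genes)]
    tfs = [f"TF{i:02d}" for i in range(n_tfs)]
    gene_res = {
        g: frozenset(f"{g}:re{j}" for j in range(res_per_gene)) for g in genes
    }
    universe = frozenset().union(*gene_res.values())
    links = REGeneLinks(universe, gene_res)

    module_genes = genes[:n_module_genes]
    planted = tfs[:n_module_tfs]
    block_of = {
        g: planted[i % n_module_tfs] for i, g in enumerate(module_genes)
    } if planted else {}

    rng = substream(seed, "fixture", "regulatory")
    hits: dict[str, set[str]] = {tf: set() for tf in tfs}
    for g in module_genes:
        tf = block_of[g]
        for re in sorted(gene_res[g]):
            if rng.random() < within_density:
                hits[tf].add(re)
    all_res = sorted(universe)
    for tf in tfs:
        mask = rng.random(len(all_res)) < background_density
        hits[tf].update(re for re, m in zip(all_res, mask) if m)
    motif_hits = REMotifHits({tf: frozenset(res) for tf, res in hits.items()})

    # oracle-predicted surviving edges (exact rational Fisher gate)
    n_universe = len(universe)
    expected_edges = []
    for tf in tfs:
        tf_res = motif_hits.hits[tf]
        for g in genes:
            cg = gene_res[g]
            a = len(cg & tf_res)
            if a == 0:
                continue
            b = len(cg) - a
            c = len(tf_res) - a
            d = n_universe - a - b - c
            if exact_fisher_greater(a, b, c, d) <= Fraction(alpha).limit_denominator(10**6):
                expected_edges.append((tf, g, a / (a + b)))

    factor = rng.standard_normal(n_samples)
    expr = np.empty((n_tfs, n_samples))
    for i, tf in enumerate(tfs):
        if tf in planted:
            expr[i] = factor + noise_sd * rng.standard_normal(n_samples)
        else:
            expr[i] = rng.standard_normal(n_samples)
    expression = pd.DataFrame(
        expr, index=pd.Index(tfs, name="gene"), columns=[f"s{j:02d}" for j in range(n_samples)]
    )

    return FixtureBundle(
        name="synthetic-regulatory",
        links=links,
        hits=motif_hits,
        expression=expression,
        planted_triplet=tuple(planted),
        planted_genes=tuple(module_genes),
        expected_edges=tuple(expected_edges),
        alpha=alpha,
        noise_sd=noise_sd,
    )
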