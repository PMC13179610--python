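"""Biological application layer: TF set search on deterministic networks.

Repeatedly runs a probing policy on a TF-gene network instance to tally
selected TF sets (triplets by default), summarizes how much of a gene set
the chosen TFs cover, compares a TF's regulation of the gene set against
a genome-wide background network, and scores triplet co-expression.

On a fixed deterministic network the greedy policies have no intrinsic
randomness; run-to-run variability is produced by seeded random
tie-breaking among candidates whose marginal scores agree within a
relative tolerance (1e-9 by default; a larger "soft" tolerance widens the
tie pool).  This randomization mechanism is this package's reconstruction
of repeated-iteration tallies and can be switched off.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .algorithms import ampcov, evaluate_probe_set, nampcov, off
from .model import ProbingInstance, WeightRealization
from .network import TFGeneNetwork
from .rng import substream

__all__ = [
    "TripletTally",
    "run_triplet_search",
    "coverage_summary",
    "background_specificity",
    "triplet_coexpression",
    "coexpression_enrichment_test",
    "random_tf_sets",
]


@dataclass(frozen=True)
class TripletTally:
    """Selection frequencies of TF sets over repeated probing runs."""

    counts: dict[tuple[str, ...], int]
    runs: tuple[dict, ...]  # per-run records: k, iteration, value, selection

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def frequencies(self) -> dict[tuple[str, ...], float]:
        tot = self.total
        return {s: c / tot for s, c in self.counts.items()}

    def modal_set(self) -> tuple[str, ...]:
        return max(sorted(self.counts), key=lambda s: self.counts[s])

    def top_sets(self, n: int = 10) -> list[tuple[tuple[str, ...], int]]:
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]


def run_triplet_search(
    instance: ProbingInstance,
    tf_ids: list[str],
    k_values: list[int],
    l: int = 3,
    iterations_per_k: int = 500,
    algorithm: str = "nampcov",
    master_seed: int = 0,
    tie_rtol: float = 1e-9,
    randomize_ties: bool = True,
) -> TripletTally:
    """Tally TF sets selected across repeated runs for each probe budget k."""
    if not instance.deterministic:
        raise ValueError("triplet search operates on deterministic network instances")
    if l > min(k_values):
        raise ValueError("l must not exceed the smallest probe budget")
    realization = WeightRealization(instance.point_weights)
    counts: Counter = Counter()
    runs: list[dict] = []
    for k in k_values:
        for it in range(iterations_per_k):
            rng = (
                substream(master_seed, "triplets", algorithm, k, it)
                if randomize_ties
                else None
            )
            if algorithm == "nampcov":
                probe_set = nampcov(instance, k, l, tie_rng=rng, tie_rtol=tie_rtol)
                run = evaluate_probe_set(probe_set, realization, l, "cov", rng, tie_rtol)
            elif algorithm == "ampcov":
                run = ampcov(instance, realization, k, l, tie_rng=rng, tie_rtol=tie_rtol)
            elif algorithm == "off":
                sel, value = off(realization, l, tie_rng=rng)
                run_sel = frozenset(sel)
                run = None
                selection = tuple(sorted(tf_ids[i] for i in run_sel))
                counts[selection] += 1
                runs.append({"k": k, "iteration": it, "value": value, "selection": selection})
                continue
            else:
                raise ValueError(f"unknown algorithm {algorithm!r}")
            selection = tuple(sorted(tf_ids[i] for i in run.selected))
            counts[selection] += 1
            runs.append({"k": k, "iteration": it, "value": run.value, "selection": selection})
    return TripletTally(dict(counts), tuple(runs))


def coverage_summary(
    selected_sets: list[tuple[str, ...]],
    network: TFGeneNetwork,
    gene_set: set[str],
) -> pd.DataFrame:
    """Fraction of the gene set covered by each selected TF set.

    A gene counts as covered when it has at least one positive-weight edge
    to a TF of the set.  Rows report the set, its size, and the fraction.
    """
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    targets = {}
    for tf, gene, _ in network.edges:
        targets.setdefault(tf, set()).add(gene)
    rows = []
    for tf_set in selected_sets:
        covered = set()
        for tf in tf_set:
            covered |= targets.get(tf, set()) & gene_set
        rows.append(
            {
                "tf_set": tuple(sorted(tf_set)),
                "set_size": len(tf_set),
                "covered_genes": len(covered),
                "fraction_covered": len(covered) / len(gene_set),
            }
        )
    return pd.DataFrame(rows)


def background_specificity(
    network_geneset: TFGeneNetwork,
    network_background: TFGeneNetwork,
    tf: str,
) -> tuple[float, float]:
    """Percent of genes regulated by the TF in the gene-set vs background network.

    Only genes with at least one linked RE (the networks' gene universes)
    enter the denominators.
    """
    if tf not in set(network_geneset.tfs) | set(network_background.tfs):
        raise KeyError(f"TF {tf!r} absent from both networks")

    def pct(net: TFGeneNetwork) -> float:
        if not net.genes:
            return 0.0
        return 100.0 * len(net.regulated_genes(tf)) / len(net.genes)

    return pct(network_geneset), pct(network_background)


def _resolve_expression(
    expr: pd.DataFrame, tf: str, dimer_map: dict[str, list[str]] | None
) -> np.ndarray:
    """Expression vector of a TF; dimers are averaged across constituents."""
    if dimer_map and tf in dimer_map:
        parts = dimer_map[tf]
        missing = [p for p in parts if p not in expr.index]
        if missing:
            raise KeyError(f"dimer constituents missing from expression table: {missing}")
        return expr.loc[parts].to_numpy(float).mean(axis=0)
    if tf not in expr.index:
        raise KeyError(f"gene {tf!r} missing from expression table")
    return expr.loc[tf].to_numpy(float)


def triplet_coexpression(
    expr: pd.DataFrame,
    triplet: tuple[str, ...],
    dimer_map: dict[str, list[str]] | None = None,
) -> float:
    """Mean pairwise Pearson correlation of the TFs in a triplet.

    Zero-variance expression vectors are reported via a warning and the
    affected pairs skipped.
    """
    if expr.index.has_duplicates:
        raise ValueError("expression table has duplicate gene ids")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    vectors = {tf: _resolve_expression(expr, tf, dimer_map) for tf in triplet}
    rs = []
    for t1, t2 in combinations(triplet, 2):
        x, y = vectors[t1], vectors[t2]
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(
                f"zero-variance expression for pair ({t1}, {t2}); pair skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        rs.append(stats.pearsonr(x, y).statistic)
    if not rs:
        raise ValueError("all pairs had zero-variance expression")
    return float(np.mean(rs))


def random_tf_sets(
    tfs: list[str], n_sets: int, set_size: int, rng: np.random.Generator
) -> list[tuple[str, ...]]:
    """Uniformly drawn TF sets used as the co-expression baseline."""
    tfs = sorted(tfs)
    return [
        tuple(sorted(rng.choice(tfs, size=set_size, replace=False)))
        for _ in range(n_sets)
    ]


def coexpression_enrichment_test(
    top_triplets: list[tuple[str, ...]],
    random_triplets: list[tuple[str, ...]],
    expr: pd.DataFrame,
    dimer_map: dict[str, list[str]] | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Two-sided Mann-Whitney U test on mean pairwise correlations.

    Compares the co-expression distribution of the top-selected triplets
    against uniformly drawn random triplets.  Returns the p-value and the
    two correlation samples.  Identical degenerate groups (all pooled
    values equal, where the tie-corrected normal approximation is
    undefined) conventionally return p = 1.
    """
    if len(top_triplets) < 3 or len(random_triplets) < 3:
        raise ValueError("need at least 3 triplets per group")
    top_r = np.array([triplet_coexpression(expr, t, dimer_map) for t in top_triplets])
    rand_r = np.array([triplet_coexpression(expr, t, dimer_map) for t in random_triplets])
    pooled = np.concatenate([top_r, rand_r])
    if np.allclose(pooled, pooled[0]):
        return 1.0, top_r, rand_r
    res = stats.mannwhitneyu(top_r, rand_r, alternative="two-sided")
    return float(res.pvalue), top_r, rand_r
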