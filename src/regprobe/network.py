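"""TF-gene network construction from regulatory-element data.

Edges between a transcription factor (TF) and a gene are weighted by the
fraction of the gene's regulatory elements (REs) carrying a predicted
binding site for the TF,

    w_{TF,G} = |c_TF| / |C_G|,

gated by a one-sided Fisher's exact test (alternative = greater) requiring
the TF's binding sites to be enriched among the gene's REs relative to the
full RE universe; non-enriched pairs get weight zero and are omitted.  The
resulting bipartite network is deterministic and loads directly as a
point-mass probing instance.

Expected input provenance: RE-gene links from an enhancer-gene prediction
method (e.g. an Activity-by-Contact-style model on H3K27ac peaks) and
binarized motif hits from a motif scanner; both arrive as headered TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .model import ProbingInstance

#: round-off guard for the inclusive p <= alpha comparison: the exact
#: hypergeometric tail can equal alpha (e.g. 1/20) while floating-point
#: evaluation lands a few ulp above it
_ALPHA_TOL = 1e-12

__all__ = [
    "REGeneLinks",
    "REMotifHits",
    "ContingencyTable",
    "TFGeneNetwork",
    "fisher_greater_p",
    "edge_weight",
    "build_network",
    "network_to_instance",
    "read_links_tsv",
    "read_hits_tsv",
    "read_bed_regions",
    "read_network_tsv",
    "write_network_tsv",
]


@dataclass(frozen=True)
class REGeneLinks:
    """RE universe plus the RE set C_G linked to every gene."""

    universe: frozenset[str]
    links: dict[str, frozenset[str]]

    def __post_init__(self):
        for gene, res in self.links.items():
            if not res <= self.universe:
                raise ValueError(f"gene {gene!r} links REs outside the universe")

    def genes_with_res(self) -> list[str]:
        return sorted(g for g, res in self.links.items() if res)


@dataclass(frozen=True)
class REMotifHits:
    """Binarized motif hits: RE sets per TF (any hit count >= 1 counts)."""

    hits: dict[str, frozenset[str]]

    def restricted(self, universe: frozenset[str]) -> "REMotifHits":
        return REMotifHits({tf: res & universe for tf, res in self.hits.items()})


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 enrichment table of a (TF, gene) pair over the RE universe.

    a: REs linked to the gene with a TFBS; b: linked without; c: unlinked
    with; d: unlinked without.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_greater_p(table: ContingencyTable) -> float:
    """One-sided (greater) Fisher exact p-value.

    Hypergeometric upper tail: probability of drawing >= a TFBS-bearing REs
    among the a+b REs linked to the gene, from a+c such REs in the universe.
    """
    return float(
        stats.hypergeom.sf(
            table.a - 1, table.universe_size, table.a + table.c, table.a + table.b
        )
    )


def _contingency(gene_res: frozenset[str], tf_res: frozenset[str], n_universe: int) -> ContingencyTable:
    a = len(gene_res & tf_res)
    b = len(gene_res) - a
    c = len(tf_res) - a
    d = n_universe - a - b - c
    return ContingencyTable(a, b, c, d)


def edge_weight(
    gene: str,
    tf: str,
    links: REGeneLinks,
    hits: REMotifHits,
    alpha: float = 0.05,
) -> float:
    """Regulatory-activity weight |c_TF|/|C_G| gated by enrichment at alpha."""
    if gene not in links.links:
        raise KeyError(f"unknown gene {gene!r}")
    if tf not in hits.hits:
        raise KeyError(f"unknown TF {tf!r}")
    gene_res = links.links[gene]
    if not gene_res:
        raise ValueError(f"gene {gene!r} has no linked REs")
    tf_res = hits.hits[tf] & links.universe
    table = _contingency(gene_res, tf_res, len(links.universe))
    if table.a == 0:
        return 0.0
    if fisher_greater_p(table) > alpha + _ALPHA_TOL:
        return 0.0
    return table.a / (table.a + table.b)


@dataclass(frozen=True)
class TFGeneNetwork:
    """Bipartite TF-gene network with strictly positive edge weights."""

    edges: tuple[tuple[str, str, float], ...]
    genes: tuple[str, ...]  # genes with at least one linked RE
    tfs: tuple[str, ...]  # TFs considered during construction
    alpha: float = 0.05
    label: str | None = None

    def __post_init__(self):
        if any(w <= 0 for _, _, w in self.edges):
            raise ValueError("network edges must have strictly positive weights")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["tf", "gene", "weight"])

    def edge_tfs(self) -> list[str]:
        return sorted({tf for tf, _, _ in self.edges})

    def gene_degrees(self) -> dict[str, int]:
        """Number of TFs with a non-zero edge, per gene (0 for uncovered genes)."""
        deg = {g: 0 for g in self.genes}
        for _, gene, _ in self.edges:
            deg[gene] = deg.get(gene, 0) + 1
        return deg

    def regulated_genes(self, tf: str) -> set[str]:
        return {g for t, g, _ in self.edges if t == tf}


def build_network(
    links: REGeneLinks,
    hits: REMotifHits,
    alpha: float = 0.05,
    tf_whitelist: set[str] | None = None,
    label: str | None = None,
) -> TFGeneNetwork:
    """Run the enrichment-gated weighting for every (TF, gene) pair.

    Output is deterministic and invariant to input row order: TFs and
    genes are processed in sorted order.  Only edges with positive weight
    surviving the Fisher gate (p <= alpha, inclusive) are emitted.
    """
    if not links.universe:
        raise ValueError("RE universe is empty")
    tfs = sorted(tf_whitelist) if tf_whitelist is not None else sorted(hits.hits)
    genes = links.genes_with_res()
    n_universe = len(links.universe)
    edges = []
    for tf in tfs:
        tf_res = hits.hits.get(tf, frozenset()) & links.universe
        if not tf_res:
            continue
        for gene in genes:
            gene_res = links.links[gene]
            table = _contingency(gene_res, tf_res, n_universe)
            if table.a == 0:
                continue
            if fisher_greater_p(table) <= alpha + _ALPHA_TOL:
                edges.append((tf, gene, table.a / (table.a + table.b)))
    return TFGeneNetwork(tuple(edges), tuple(genes), tuple(tfs), alpha, label)


def network_to_instance(
    network: TFGeneNetwork,
    gene_subset: set[str] | None = None,
) -> tuple[ProbingInstance, list[str], list[str]]:
    """Convert a network into a deterministic probing instance.

    Regulators are the TFs with at least one edge to the retained genes,
    positions the retained genes; missing edges get weight 0.  Returns the
    instance together with the regulator and position identifier lists.
    """
    genes = [g for g in network.genes if gene_subset is None or g in gene_subset]
    gene_pos = {g: i for i, g in enumerate(genes)}
    kept = [(t, g, w) for t, g, w in network.edges if g in gene_pos]
    tfs = sorted({t for t, _, _ in kept})
    if not tfs or not genes:
        raise ValueError("network is empty after gene subsetting")
    tf_pos = {t: i for i, t in enumerate(tfs)}
    W = np.zeros((len(tfs), len(genes)))
    for t, g, w in kept:
        W[tf_pos[t], gene_pos[g]] = w
    return ProbingInstance.from_weights(W), tfs, genes


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_links_tsv(path: str | Path) -> REGeneLinks:
    """Headered TSV with columns ``re_id`` and ``gene_id``.

    The RE universe is the set of all REs appearing in the file.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"re_id", "gene_id"} <= set(df.columns):
        raise ValueError("links TSV must have columns re_id, gene_id")
    universe = frozenset(df["re_id"])
    links = {
        gene: frozenset(sub["re_id"])
        for gene, sub in df.groupby("gene_id", sort=True)
    }
    return REGeneLinks(universe, links)


def read_hits_tsv(path: str | Path) -> REMotifHits:
    """Headered TSV with columns ``re_id`` and ``tf_id`` (one row per hit)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"re_id", "tf_id"} <= set(df.columns):
        raise ValueError("hits TSV must have columns re_id, tf_id")
    hits = {
        tf: frozenset(sub["re_id"])
        for tf, sub in df.groupby("tf_id", sort=True)
    }
    return REMotifHits(hits)


def read_bed_regions(path: str | Path) -> list[str]:
    """Reduce BED3 regions (0-based half-open, unstranded) to identifiers."""
    ids = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        chrom, start, end = line.split("\t")[:3]
        ids.append(f"{chrom}:{start}-{end}")
    return ids


def write_network_tsv(network: TFGeneNetwork, path: str | Path, sidecar: bool = True) -> None:
    network.to_dataframe().to_csv(path, sep="\t", index=False)
    if sidecar:
        meta = {
            "alpha": network.alpha,
            "label": network.label,
            "n_edges": len(network.edges),
            "n_genes": len(network.genes),
            "n_tfs": len(network.tfs),
            "genes": list(network.genes),
            "tfs": list(network.tfs),
        }
        Path(str(path) + ".json").write_text(json.dumps(meta))


def read_network_tsv(path: str | Path, alpha: float = 0.05) -> TFGeneNetwork:
    df = pd.read_csv(path, sep="\t")
    if not {"tf", "gene", "weight"} <= set(df.columns):
        raise ValueError("network TSV must have columns tf, gene, weight")
    if (df["weight"] <= 0).any():
        raise ValueError("network edge weights must be strictly positive")
    edges = tuple(
        (str(t), str(g), float(w)) for t, g, w in df.itertuples(index=False)
    )
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        return TFGeneNetwork(
            edges,
            tuple(meta.get("genes", sorted({g for _, g, _ in edges}))),
            tuple(meta.get("tfs", sorted({t for t, _, _ in edges}))),
            float(meta.get("alpha", alpha)),
            meta.get("label"),
        )
    genes = tuple(sorted({g for _, g, _ in edges}))
    tfs = tuple(sorted({t for t, _, _ in edges}))
    return TFGeneNetwork(edges, genes, tfs, alpha)
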