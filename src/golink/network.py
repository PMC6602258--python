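"""Thresholded gene networks, community detection, and query tables.

A gene network keeps *every* input gene as a node and draws an edge
between two genes iff their cosine similarity reaches a user-chosen
cutoff ``c`` (edges at exactly ``c`` are included).  In practice most
genes end up isolated at high-confidence cutoffs, and that sparsity is
informative, so isolated nodes are retained and reported as singleton
communities.

Communities are found by asynchronous label propagation: every node
starts with a unique label and repeatedly adopts the label that is most
frequent among its neighbours, in a seeded random order with seeded
random tie-breaking, until every node's label is already maximal among
its neighbours.  A community's GO enrichment is the mean of its genes'
association p-values per GO term, with never-observed pairs counted as 1
for a conservative call.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from golink.association import PValueMatrix, SimilarityMatrix, select_top_go

__all__ = [
    "GeneNetwork",
    "CommunityPartition",
    "LayoutConfig",
    "build_network",
    "label_propagation",
    "is_label_stable",
    "community_enrichment",
    "bonferroni",
    "gene_query",
    "go_query",
    "gene_go_query",
    "shared_go",
    "fr_layout",
    "percentile_edge_comparison",
]


@dataclass
class GeneNetwork:
    """A weighted gene graph plus the cutoff that produced it."""

    graph: nx.Graph
    cutoff: float

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.graph.nodes)


def build_network(sim: SimilarityMatrix, cutoff: float) -> GeneNetwork:
    """Threshold a similarity matrix into a network.

    An edge ``(i, i')`` is present iff ``gamma >= cutoff`` and neither gene
    is flagged undefined.  All input genes are kept as nodes, so isolated
    genes remain visible.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in [0, 1], got {cutoff}")
    G = nx.Graph(cutoff=cutoff)
    G.add_nodes_from(sim.genes)
    n = len(sim.genes)
    for i in range(n):
        gi = sim.genes[i]
        if not sim.is_defined(gi):
            continue
        for j in range(i + 1, n):
            gj = sim.genes[j]
            if not sim.is_defined(gj):
                continue
            gamma = sim.values[i, j]
            if gamma >= cutoff:
                G.add_edge(gi, gj, weight=float(gamma))
    return GeneNetwork(graph=G, cutoff=cutoff)


@dataclass
class CommunityPartition:
    """A dense labelling of every network node, with the seed that made it."""

    labels: dict[str, int]
    seed: int | None = None
    converged: bool = True

    def communities(self) -> list[list[str]]:
        """Members per label, each sorted; list index equals the label."""
        groups: dict[int, list[str]] = {}
        for gene, lab in self.labels.items():
            groups.setdefault(lab, []).append(gene)
        return [sorted(groups[lab]) for lab in sorted(groups)]

    @property
    def n_communities(self) -> int:
        return len(set(self.labels.values()))


def is_label_stable(graph: nx.Graph, labels: dict[str, int]) -> bool:
    """True iff every node's label is among the most frequent of its neighbours."""
    for node in graph:
        nbrs = list(graph[node])
        if not nbrs:
            continue
        freq = Counter(labels[n] for n in nbrs)
        if freq[labels[node]] != max(freq.values()):
            return False
    return True


def _densify(labels: dict[str, int]) -> dict[str, int]:
    # stable re-indexing: communities ordered by their smallest member id
    groups: dict[int, list[str]] = {}
    for gene, lab in labels.items():
        groups.setdefault(lab, []).append(gene)
    ordered = sorted(groups.values(), key=min)
    return {gene: i for i, members in enumerate(ordered) for gene in members}


def label_propagation(
    net: GeneNetwork,
    seed: int = 0,
    max_iter: int = 100,
) -> CommunityPartition:
    """Asynchronous label propagation community detection.

    Each node starts with a unique label.  Sweeps visit the nodes in a
    freshly shuffled seeded order; each visited node adopts a label drawn
    uniformly (seeded) from the most frequent labels among its neighbours.
    The algorithm stops once every node's label is maximal among its
    neighbours, or after ``max_iter`` sweeps with a convergence warning
    (oscillation is possible on bipartite-like structures).  Isolated nodes
    keep their unique labels.  Labels are re-indexed densely, communities
    ordered by their smallest member, so the output is reproducible.
    """
    if max_iter < 1:
        raise ValueError(f"max_iter must be >= 1, got {max_iter}")
    G = net.graph
    rng = np.random.default_rng(seed)
    nodes = sorted(G.nodes)
    labels = {node: i for i, node in enumerate(nodes)}
    converged = False
    for _ in range(max_iter):
        if is_label_stable(G, labels):
            converged = True
            break
        for idx in rng.permutation(len(nodes)):
            node = nodes[idx]
            nbrs = list(G[node])
            if not nbrs:
                continue
            freq = Counter(labels[n] for n in nbrs)
            best = max(freq.values())
            candidates = sorted(lab for lab, c in freq.items() if c == best)
            labels[node] = candidates[int(rng.integers(len(candidates)))]
    if not converged:
        converged = is_label_stable(G, labels)
    if not converged:
        warnings.warn(
            f"label propagation did not converge within {max_iter} sweeps",
            stacklevel=2,
        )
    return CommunityPartition(labels=_densify(labels), seed=seed, converged=converged)


def community_enrichment(
    pmat: PValueMatrix,
    part: CommunityPartition,
    gos: list[str] | None = None,
) -> pd.DataFrame:
    """Mean association p-value per (community, GO term).

    Missing gene-GO pairs count as p = 1, so a community can only look
    enriched for a term its members were actually observed with.  Rows are
    sorted by community, then ascending mean p, then GO id.
    """
    unknown = sorted(g for g in part.labels if g not in pmat.gene_set)
    if unknown:
        raise ValueError(f"partition gene(s) missing from the p-value matrix: {', '.join(unknown)}")
    if gos is None:
        gos = list(pmat.gos)
    rows = []
    for label, members in enumerate(part.communities()):
        profiles = [pmat.profile(g) for g in members]
        m = len(members)
        for go in gos:
            mean_p = sum(prof.get(go, 1.0) for prof in profiles) / m
            rows.append((label, go, mean_p))
    df = pd.DataFrame(rows, columns=["community", "go_id", "mean_p"])
    return df.sort_values(
        ["community", "mean_p", "go_id"], ignore_index=True
    )


def bonferroni(p: float, m: int) -> float:
    """Bonferroni adjustment ``min(1, m * p)`` for a family of *m* tests."""
    if m < 1:
        raise ValueError(f"family size m must be >= 1, got {m}")
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must lie in (0, 1], got {p}")
    return min(1.0, m * p)


def gene_query(pmat: PValueMatrix, gene: str, m: int | None = None) -> pd.DataFrame:
    """GO terms associated with one gene, most significant first.

    The Bonferroni family size defaults to the number of GO terms in the
    matrix index (every term the gene could have been tested against).
    """
    if gene not in pmat.gene_set:
        raise KeyError(f"unknown gene id: {gene}")
    if m is None:
        m = max(len(pmat.gos), 1)
    rows = [
        (go, p, bonferroni(p, m))
        for go, p in pmat.profile(gene).items()
    ]
    df = pd.DataFrame(rows, columns=["go_id", "p", "p_bonferroni"])
    return df.sort_values(["p", "go_id"], ignore_index=True)


def go_query(pmat: PValueMatrix, go: str, m: int | None = None) -> pd.DataFrame:
    """Genes associated with one GO term, most significant first."""
    if go not in pmat.go_set:
        raise KeyError(f"unknown GO id: {go}")
    if m is None:
        m = max(len(pmat.genes), 1)
    rows = [
        (g, p, bonferroni(p, m))
        for (g, t), p in pmat.p.items()
        if t == go
    ]
    df = pd.DataFrame(rows, columns=["gene", "p", "p_bonferroni"])
    return df.sort_values(["p", "gene"], ignore_index=True)


def gene_go_query(
    pmat: PValueMatrix,
    genes: list[str],
    gos: list[str] | str = "all",
    k: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """P-values between a gene list and a GO list (or all GO terms).

    Returns ``(long, matrix)``: a long table of the stored pairs sorted by
    ascending p (ties broken by gene then GO id), and a dense gene x GO
    frame with missing pairs as NaN.  When *k* is given the GO columns are
    restricted to the *k* terms with the smallest average p over the genes.
    """
    genes = list(genes)
    unknown = sorted(set(g for g in genes if g not in pmat.gene_set))
    if isinstance(gos, str):
        if gos != "all":
            raise ValueError("gos must be a list of GO ids or the string 'all'")
        go_list = list(pmat.gos)
    else:
        go_list = list(gos)
        unknown += sorted(set(t for t in go_list if t not in pmat.go_set))
    if unknown:
        raise ValueError(f"unknown id(s): {', '.join(unknown)}")
    if k is not None:
        go_list = select_top_go(pmat, genes, k)
    go_set = set(go_list)
    rows = [
        (g, go, p)
        for g in genes
        for go, p in pmat.profile(g).items()
        if go in go_set
    ]
    long = pd.DataFrame(rows, columns=["gene", "go_id", "p"])
    long = long.sort_values(["p", "gene", "go_id"], ignore_index=True)
    matrix = pd.DataFrame(
        [[pmat.p.get((g, go), np.nan) for go in go_list] for g in genes],
        index=pd.Index(genes, name="gene"),
        columns=go_list,
    )
    return long, matrix


def shared_go(
    pmat: PValueMatrix,
    gene_a: str,
    gene_b: str,
    top_n: int = 10,
) -> pd.DataFrame:
    """GO terms observed with *both* genes, with both p-values.

    Sorted by the smaller of the two p-values, truncated to ``top_n`` rows.
    """
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    for g in (gene_a, gene_b):
        if g not in pmat.gene_set:
            raise KeyError(f"unknown gene id: {g}")
    prof_a = pmat.profile(gene_a)
    prof_b = pmat.profile(gene_b)
    rows = [
        (go, prof_a[go], prof_b[go], min(prof_a[go], prof_b[go]))
        for go in prof_a.keys() & prof_b.keys()
    ]
    df = pd.DataFrame(rows, columns=["go_id", "p_a", "p_b", "min_p"])
    return df.sort_values(["min_p", "go_id"], ignore_index=True).head(top_n)


@dataclass
class LayoutConfig:
    """Parameters for the force-directed layout.

    ``k`` is the optimal node spacing of the Fruchterman-Reingold layout:
    larger values spread the drawing out, smaller values pack it tighter.
    """

    k: float = 1.0
    seed: int = 0
    iterations: int = 50

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"layout spacing k must be > 0, got {self.k}")
        if self.iterations < 1:
            raise ValueError(f"iterations must be >= 1, got {self.iterations}")


def fr_layout(net: GeneNetwork, cfg: LayoutConfig | None = None) -> dict[str, tuple[float, float]]:
    """Fruchterman-Reingold coordinates for every node (seeded, deterministic).

    Coordinates are returned in the layout's natural units (no final
    rescaling), so ``k`` keeps its meaning as the optimal inter-node
    distance: larger ``k`` genuinely spreads the drawing out.
    """
    cfg = cfg or LayoutConfig()
    pos = nx.spring_layout(
        net.graph, k=cfg.k, iterations=cfg.iterations, seed=cfg.seed,
        weight="weight", scale=None,
    )
    return {node: (float(xy[0]), float(xy[1])) for node, xy in pos.items()}


def _count_edges(
    sim: SimilarityMatrix, cutoff: float, within: Sequence[str] | None
) -> int:
    genes = sim.genes if within is None else [g for g in within if g in sim.genes]
    idx = [sim.genes.index(g) for g in genes if sim.is_defined(g)]
    count = 0
    for a in range(len(idx)):
        row = sim.values[idx[a]]
        for b in range(a + 1, len(idx)):
            if row[idx[b]] >= cutoff:
                count += 1
    return count


def percentile_edge_comparison(
    sim_a: SimilarityMatrix,
    sim_b: SimilarityMatrix,
    qs: Sequence[float],
    method: str = "linear",
    within: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Edge counts of two similarity measures at matched percentile cutoffs.

    For each level ``q`` the cutoff of each matrix is the ``q``-th empirical
    percentile of *its own* full pair-similarity distribution, which makes
    edge counts comparable across measures with very different scales.  When
    ``within`` is given, edges are counted only among that gene subset (a
    signature of interest) while the cutoffs still come from the full
    distributions -- the standard way to compare how richly two measures
    connect a related gene set relative to their overall backgrounds.
    Returns a frame with columns ``q``, ``cutoff_a``, ``edges_a``,
    ``cutoff_b``, ``edges_b``.
    """
    from golink.association import similarity_percentiles

    rows = []
    vals_a = sim_a.pair_values()
    vals_b = sim_b.pair_values()
    for q in qs:
        cut_a = min(similarity_percentiles(vals_a, [q], method=method)[0], 1.0)
        cut_b = min(similarity_percentiles(vals_b, [q], method=method)[0], 1.0)
        rows.append(
            (
                q,
                cut_a,
                _count_edges(sim_a, cut_a, within),
                cut_b,
                _count_edges(sim_b, cut_b, within),
            )
        )
    return pd.DataFrame(rows, columns=["q", "cutoff_a", "edges_a", "cutoff_b", "edges_b"])
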