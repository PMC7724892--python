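"""Within-module gene networks and edge-percolated-component centrality.

A gene-level Bayesian network is learned on the expression submatrix of a
module; its undirected skeleton is the gene network.  EPC centrality of a
node is the expected number of other nodes left in its connected component
after each edge is independently retained with probability p — a global
measure of how strongly a gene ties the module network together.  Hub
genes are the top-scoring nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .bayesnet import learn_averaged_network
from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)


def _module_core(matrix: ExpressionMatrix, genes: list[str], k: int) -> list[str]:
    """Top-k module genes by module membership |kME| (input order on ties)."""
    sub = matrix.values.loc[genes].to_numpy()
    sub = (sub - sub.mean(1, keepdims=True)) / sub.std(1, ddof=1, keepdims=True)
    me = np.linalg.svd(sub, full_matrices=False)[2][0]
    kme = np.abs(sub @ me) / (np.linalg.norm(sub, axis=1) * np.linalg.norm(me))
    order = np.argsort(-kme, kind="stable")[:k]
    keep = np.zeros(len(genes), dtype=bool)
    keep[order] = True
    return [g for g, flag in zip(genes, keep) if flag]


def build_gene_network(
    matrix: ExpressionMatrix,
    module_genes: list[str],
    keep_genes: list[str] | None = None,
    n_restarts: int = 20,
    arc_threshold: float = 0.5,
    seed: int = 0,
    init_arc_prob: float = 0.02,
    max_genes: int | None = 150,
) -> nx.Graph:
    """Undirected skeleton of an averaged gene-level Bayesian network.

    Learns the averaged DAG on the module submatrix (samples x genes),
    optionally restricts to a caller-supplied keep list (e.g. a
    literature-based gene filter), and drops isolated nodes.  Modules
    larger than ``max_genes`` are first reduced to their core — the top
    genes by module membership |kME| — mirroring the usual practice of
    pruning a large module to a tractable, well-connected center before
    gene-level structure learning.
    """
    module_genes = list(module_genes)
    missing = [g for g in module_genes if g not in matrix.gene_ids]
    if missing:
        raise KeyError(f"module genes absent from matrix: {missing[:10]}")
    if len(module_genes) < 3:
        raise ValueError(f"need >= 3 genes, got {len(module_genes)}")
    if max_genes is not None and len(module_genes) > max_genes:
        logger.info("reducing module from %d to its %d-gene |kME| core",
                    len(module_genes), max_genes)
        module_genes = _module_core(matrix, module_genes, max_genes)
    data = matrix.values.loc[module_genes].T
    dag, strength = learn_averaged_network(
        data,
        n_restarts=n_restarts,
        arc_threshold=arc_threshold,
        seed=seed,
        init_arc_prob=init_arc_prob,
    )
    skeleton = nx.Graph()
    skeleton.add_nodes_from(dag.nodes)
    for u, v, attrs in dag.edges(data=True):
        skeleton.add_edge(u, v, frequency=attrs.get("frequency", 1.0))
    if keep_genes is not None:
        keep = set(keep_genes)
        skeleton = skeleton.subgraph([n for n in skeleton if n in keep]).copy()
    isolated = list(nx.isolates(skeleton))
    if isolated:
        logger.info("dropping %d isolated genes from skeleton", len(isolated))
        skeleton.remove_nodes_from(isolated)
    return skeleton


@dataclass
class EPCScores:
    """Per-gene EPC centrality with the sampling settings that produced it.

    ``scores_se`` holds the Monte-Carlo standard error of each mean (zero
    for exact enumeration).
    """

    scores: pd.Series
    p: float
    n_samples: int
    seed: int | None = None
    exact: bool = False
    scores_se: pd.Series | None = None


class _UnionFind:
    __slots__ = ("parent", "size")

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, a: int) -> int:
        parent = self.parent
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]


def _component_sizes(n: int, edges: list[tuple[int, int]]) -> list[int]:
    uf = _UnionFind(n)
    for a, b in edges:
        uf.union(a, b)
    return [uf.size[uf.find(i)] for i in range(n)]


def epc_score(
    net: nx.Graph,
    p: float = 0.5,
    n_samples: int = 1000,
    seed: int = 0,
) -> EPCScores:
    """Monte-Carlo EPC: mean reachable-other-node count under edge percolation.

    Each realization keeps every edge independently with probability ``p``;
    EPC(v) averages the size of v's connected component minus one.
    Deterministic given ``seed``.
    """
    if not 0 < p < 1:
        raise ValueError(f"retention probability must be in (0, 1), got {p}")
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    nodes = sorted(net.nodes)
    if not nodes:
        logger.warning("empty graph: all EPC scores are 0")
        return EPCScores(pd.Series(dtype=float, name="epc"), p, n_samples, seed)
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in sorted(map(sorted, net.edges))]
    rng = np.random.default_rng(seed)
    totals = np.zeros(len(nodes))
    totals_sq = np.zeros(len(nodes))
    if edges:
        masks = rng.random((n_samples, len(edges))) < p
        for row in masks:
            kept = [e for e, keep in zip(edges, row) if keep]
            counts = np.array(_component_sizes(len(nodes), kept)) - 1
            totals += counts
            totals_sq += counts**2
    mean = totals / n_samples
    var = np.maximum(totals_sq / n_samples - mean**2, 0.0)
    se = np.sqrt(var / n_samples)
    scores = pd.Series(mean, index=nodes, name="epc")
    return EPCScores(scores, p, n_samples, seed,
                     scores_se=pd.Series(se, index=nodes, name="epc_se"))


def epc_exact(net: nx.Graph, p: float = 0.5, max_edges: int = 20) -> EPCScores:
    """Exact EPC by enumerating every edge subset (|E| <= ``max_edges``)."""
    if not 0 < p < 1:
        raise ValueError(f"retention probability must be in (0, 1), got {p}")
    nodes = sorted(net.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in sorted(map(sorted, net.edges))]
    m = len(edges)
    if m > max_edges:
        raise ValueError(f"{m} edges exceeds enumeration limit {max_edges}")
    expected = np.zeros(len(nodes))
    for mask in range(1 << m):
        kept = [edges[i] for i in range(m) if mask >> i & 1]
        k = len(kept)
        weight = p**k * (1.0 - p) ** (m - k)
        expected += weight * (np.array(_component_sizes(len(nodes), kept)) - 1)
    return EPCScores(pd.Series(expected, index=nodes, name="epc"), p, 0, exact=True)


def select_hubs(
    scores: EPCScores, net: nx.Graph, k: int = 6
) -> tuple[list[str], nx.Graph]:
    """Top-k EPC genes and their expanded subnetwork.

    Ties break by degree (descending) then node id.  The subnetwork is the
    induced subgraph on the hubs plus all their direct neighbors; every
    node carries its EPC score and rank (1 = most central) as attributes.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > len(scores.scores):
        raise ValueError(f"k={k} exceeds {len(scores.scores)} scored nodes")
    ranked = sorted(
        scores.scores.index,
        key=lambda v: (-scores.scores[v], -net.degree(v) if v in net else 0, str(v)),
    )
    hubs = ranked[:k]
    members = set(hubs)
    for h in hubs:
        if h in net:
            members |= set(net.neighbors(h))
    sub = net.subgraph(members).copy()
    rank = {v: i + 1 for i, v in enumerate(ranked)}
    for v in sub.nodes:
        sub.nodes[v]["epc"] = float(scores.scores.get(v, 0.0))
        sub.nodes[v]["epc_rank"] = int(rank.get(v, 0))
        sub.nodes[v]["is_hub"] = v in set(hubs)
    return hubs, sub
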