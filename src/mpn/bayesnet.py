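"""Score-based Gaussian Bayesian-network structure learning.

Hill climbing over single-arc add/delete/reverse moves under a decomposable
Gaussian BIC score, restarted from random DAGs and model-averaged by arc
frequency; Markov-blanket queries; and the module-prioritization rule that
ranks co-expression modules by how much of the phenotype set (reserve,
MMSE, Braak, NFT) sits inside their Markov blankets.

All variables — eigengenes, ordinal stages, and the binary reserve label —
are standardized and scored in one homogeneous linear-Gaussian family.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_EPS = 1e-10          # minimum score improvement accepted by hill climbing
_VAR_FLOOR = 1e-12    # residual-variance floor for degenerate fits


class GaussianBICScorer:
    """Decomposable Gaussian BIC over a data table.

    Local score of a node given a parent set is the maximized Gaussian
    log-likelihood of the node regressed on its parents minus
    0.5 * log(n) * (#parents + 2) — the +2 counting intercept and residual
    variance.  Local scores are cached by (node, parent set); fits run on
    the precomputed centered Gram matrix, so each one is a small solve.
    """

    def __init__(self, data: pd.DataFrame):
        if data.shape[1] == 0 or data.shape[0] < 3:
            raise ValueError("data table needs >= 1 column and >= 3 rows")
        self.nodes = list(data.columns)
        self.n = len(data)
        x = data.to_numpy(dtype=float)
        xc = x - x.mean(axis=0)
        self._gram = xc.T @ xc
        self._index = {c: i for i, c in enumerate(self.nodes)}
        self._cache: dict[tuple[str, frozenset], float] = {}

    def local_score(self, node: str, parents: frozenset) -> float:
        key = (node, parents)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        i = self._index[node]
        n = self.n
        syy = self._gram[i, i]
        if parents:
            p_idx = [self._index[p] for p in parents]
            spp = self._gram[np.ix_(p_idx, p_idx)]
            spy = self._gram[p_idx, i]
            try:
                beta = np.linalg.solve(spp, spy)
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    f"singular parent design for node {node!r}, parents {sorted(parents)}"
                ) from exc
            rss = syy - spy @ beta
        else:
            rss = syy
        sigma2 = max(rss / n, _VAR_FLOOR)
        loglik = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
        score = loglik - 0.5 * math.log(n) * (len(parents) + 2)
        self._cache[key] = score
        return score

    def score(self, dag: nx.DiGraph) -> float:
        """Total decomposable score; nodes absent from the DAG are marginal."""
        total = 0.0
        for node in self.nodes:
            parents = frozenset(dag.predecessors(node)) if dag.has_node(node) else frozenset()
            total += self.local_score(node, parents)
        return total

    def add_deltas(self, node: str, parents: frozenset) -> np.ndarray:
        """Score change of adding each candidate parent to ``node``.

        Returns an array over all variables (in column order) holding the
        local-score delta of the move parents -> parents + {u}; entries for
        ``node`` itself, current parents, and (near-)collinear candidates
        are -inf.  Uses the Gram-matrix identity
        rss(node | P + u) = rss(node | P) - c_uv^2 / c_uu with c the
        covariance conditional on P, so one parent set prices all
        candidates at once.
        """
        i = self._index[node]
        n = self.n
        gram = self._gram
        diag = np.diag(gram)
        if parents:
            p_idx = [self._index[p] for p in parents]
            spp = gram[np.ix_(p_idx, p_idx)]
            try:
                w = np.linalg.solve(spp, gram[p_idx, :])
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    f"singular parent design for node {node!r}, parents {sorted(parents)}"
                ) from exc
            c_col = gram[:, i] - gram[:, p_idx] @ w[:, i]
            c_diag = diag - np.einsum("ij,ij->j", gram[p_idx, :], w)
            rss_old = c_col[i]
        else:
            c_col = gram[:, i].copy()
            c_diag = diag.copy()
            rss_old = gram[i, i]
        sigma_old = max(rss_old / n, _VAR_FLOOR)
        with np.errstate(divide="ignore", invalid="ignore"):
            rss_new = rss_old - np.where(c_diag > _VAR_FLOOR, c_col**2 / c_diag, 0.0)
        sigma_new = np.maximum(rss_new / n, _VAR_FLOOR)
        deltas = -0.5 * n * (np.log(sigma_new) - math.log(sigma_old)) - 0.5 * math.log(n)
        deltas[c_diag <= _VAR_FLOOR] = -np.inf
        deltas[i] = -np.inf
        for p in parents:
            deltas[self._index[p]] = -np.inf
        return deltas


def bic_gaussian_score(data: pd.DataFrame, dag: nx.DiGraph) -> float:
    """Convenience wrapper: Gaussian BIC of ``dag`` on ``data``."""
    return GaussianBICScorer(data).score(dag)


def _closure(adj: np.ndarray) -> np.ndarray:
    """Boolean transitive closure (reach[i, j]: i reaches j, >= 1 edge)."""
    reach = adj.copy()
    while True:
        new = reach | (reach.astype(np.uint8) @ reach.astype(np.uint8)).astype(bool)
        if (new == reach).all():
            return reach
        reach = new


def hill_climb(
    data: pd.DataFrame,
    init: nx.DiGraph | None = None,
    max_iter: int = 500,
    scorer: GaussianBICScorer | None = None,
) -> nx.DiGraph:
    """Greedy single-arc hill climbing to a local score optimum.

    At each step the best score-improving arc addition, deletion, or
    reversal that preserves acyclicity is applied; ties break on the
    lexicographic (operation, from, to) order so runs are deterministic.
    The accepted-move score trajectory is strictly increasing.
    """
    scorer = scorer or GaussianBICScorer(data)
    nodes = scorer.nodes
    index = {v: i for i, v in enumerate(nodes)}
    dag = nx.DiGraph()
    dag.add_nodes_from(nodes)
    if init is not None:
        if not nx.is_directed_acyclic_graph(init):
            raise ValueError("init graph must be acyclic")
        dag.add_edges_from(init.edges)
    parent_sets = {v: frozenset(dag.predecessors(v)) for v in nodes}
    ls = scorer.local_score
    p = len(nodes)
    # add_mat[child, u] = delta of adding u -> child; rows refreshed when a
    # child's parent set changes
    add_mat = np.vstack([scorer.add_deltas(v, parent_sets[v]) for v in nodes])
    adj = np.zeros((p, p), dtype=bool)
    for u, v in dag.edges:
        adj[index[u], index[v]] = True
    reach = _closure(adj)

    converged = False
    for _ in range(max_iter):
        best = None  # (delta, (op, u, v))
        # adding u -> v closes a cycle iff v already reaches u;
        # add_mat is [child v, parent u], so the mask is reach[v, u]
        legal = np.where(reach, -np.inf, add_mat)
        vi, ui = np.unravel_index(int(np.argmax(legal)), legal.shape)
        if legal[vi, ui] > _EPS:
            best = (float(legal[vi, ui]), ("add", nodes[ui], nodes[vi]))
        for u, v in sorted(dag.edges):
            pv = parent_sets[v]
            del_delta = ls(v, pv - {u}) - ls(v, pv)
            if del_delta > _EPS and (best is None or del_delta > best[0] + 1e-12):
                best = (del_delta, ("delete", u, v))
            # reversal u->v => v->u: illegal iff an alternate u ~> v path
            # exists; in a DAG such a path runs through another successor of u
            iu, iv = index[u], index[v]
            succ = adj[iu].copy()
            succ[iv] = False
            if not reach[succ, iv].any():
                delta = del_delta + float(add_mat[iu, iv])
                if delta > _EPS and (best is None or delta > best[0] + 1e-12):
                    best = (delta, ("reverse", u, v))
        if best is None:
            converged = True
            break
        _, (op, u, v) = best
        iu, iv = index[u], index[v]
        if op == "add":
            dag.add_edge(u, v)
            adj[iu, iv] = True
            parent_sets[v] = parent_sets[v] | {u}
            add_mat[iv] = scorer.add_deltas(v, parent_sets[v])
            # incremental closure: ancestors-of-u (and u) reach v's cone
            src = reach[:, iu].copy(); src[iu] = True
            dst = reach[iv].copy(); dst[iv] = True
            reach |= np.outer(src, dst)
        elif op == "delete":
            dag.remove_edge(u, v)
            adj[iu, iv] = False
            parent_sets[v] = parent_sets[v] - {u}
            add_mat[iv] = scorer.add_deltas(v, parent_sets[v])
            reach = _closure(adj)
        else:
            dag.remove_edge(u, v)
            dag.add_edge(v, u)
            adj[iu, iv] = False
            adj[iv, iu] = True
            parent_sets[v] = parent_sets[v] - {u}
            parent_sets[u] = parent_sets[u] | {v}
            add_mat[iv] = scorer.add_deltas(v, parent_sets[v])
            add_mat[iu] = scorer.add_deltas(u, parent_sets[u])
            reach = _closure(adj)
    if not converged:
        logger.debug("hill climb hit max_iter=%d before convergence", max_iter)
        dag.graph["converged"] = False
    else:
        dag.graph["converged"] = True
    return dag


def random_dag(nodes: list, arc_prob: float, rng: np.random.Generator) -> nx.DiGraph:
    """Random DAG: arcs sampled consistently with a random topological order."""
    order = list(rng.permutation(nodes))
    dag = nx.DiGraph()
    dag.add_nodes_from(nodes)
    for i, u in enumerate(order):
        for v in order[i + 1:]:
            if rng.random() < arc_prob:
                dag.add_edge(u, v)
    return dag


@dataclass
class ArcStrengthTable:
    """Arc frequencies across restarts.

    ``directed`` maps ordered pairs to the fraction of learned networks
    containing the arc; ``n_restarts`` is the tally denominator.
    """

    directed: dict[tuple[str, str], float]
    n_restarts: int

    def undirected(self) -> dict[frozenset, float]:
        totals: dict[frozenset, float] = {}
        for (u, v), f in self.directed.items():
            key = frozenset((u, v))
            totals[key] = totals.get(key, 0.0) + f
        return totals

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"from": u, "to": v, "frequency": f}
            for (u, v), f in sorted(self.directed.items())
        ]
        return pd.DataFrame(rows, columns=["from", "to", "frequency"])


def learn_averaged_network(
    data: pd.DataFrame,
    n_restarts: int = 200,
    arc_threshold: float = 0.5,
    seed: int = 0,
    init_arc_prob: float = 0.1,
    max_iter: int = 500,
    bootstrap: bool = True,
) -> tuple[nx.DiGraph, ArcStrengthTable]:
    """Model-averaged network from randomly restarted hill climbs.

    Each restart starts hill climbing from a random DAG (per-arc inclusion
    probability ``init_arc_prob`` along a random topological order, which
    guarantees acyclicity) and, with ``bootstrap=True``, fits a
    nonparametric bootstrap resample of the rows — the standard
    bootstrap realization of Bayesian model averaging, which strips arcs
    that only reflect sampling noise of one draw.  Arc frequencies are
    tallied over all restarts; undirected pairs with total frequency >=
    ``arc_threshold`` are kept and directed by majority (lexicographic
    tie-break).  Any induced cycle is broken by removing its
    lowest-frequency arc.  Deterministic given seed.
    """
    if n_restarts < 1:
        raise ValueError(f"n_restarts must be >= 1, got {n_restarts}")
    rng = np.random.default_rng(seed)
    scorer = GaussianBICScorer(data)
    nodes = scorer.nodes
    counts: dict[tuple[str, str], int] = {}
    truncated = 0
    for _ in range(n_restarts):
        init = random_dag(nodes, init_arc_prob, rng)
        if bootstrap:
            idx = rng.integers(0, len(data), len(data))
            restart_scorer = GaussianBICScorer(data.iloc[idx])
        else:
            restart_scorer = scorer
        learned = hill_climb(data, init=init, max_iter=max_iter, scorer=restart_scorer)
        truncated += not learned.graph.get("converged", True)
        for arc in learned.edges:
            counts[arc] = counts.get(arc, 0) + 1
    if truncated:
        logger.warning("%d/%d restarts hit max_iter=%d before convergence",
                       truncated, n_restarts, max_iter)
    strength = ArcStrengthTable(
        {arc: c / n_restarts for arc, c in counts.items()}, n_restarts
    )

    averaged = nx.DiGraph()
    averaged.add_nodes_from(nodes)
    freq = strength.directed
    for pair, total in sorted(strength.undirected().items(), key=lambda kv: sorted(kv[0])):
        if total < arc_threshold:
            continue
        u, v = sorted(pair)
        f_uv, f_vu = freq.get((u, v), 0.0), freq.get((v, u), 0.0)
        arc = (u, v) if f_uv >= f_vu else (v, u)
        averaged.add_edge(*arc, frequency=total)
    while not nx.is_directed_acyclic_graph(averaged):
        cycle = nx.find_cycle(averaged)
        weakest = min(cycle, key=lambda e: (freq.get((e[0], e[1]), 0.0), e))
        logger.info("breaking averaged-network cycle at arc %s", weakest[:2])
        averaged.remove_edge(weakest[0], weakest[1])
    return averaged, strength


def markov_blanket(dag: nx.DiGraph, node: str) -> set:
    """Parents, children, and co-parents of children of ``node``."""
    if node not in dag:
        raise KeyError(f"node {node!r} not in graph")
    blanket = set(dag.predecessors(node)) | set(dag.successors(node))
    for child in dag.successors(node):
        blanket |= set(dag.predecessors(child))
    blanket.discard(node)
    return blanket


def prioritize_modules(
    dag: nx.DiGraph,
    strength: ArcStrengthTable,
    module_nodes: list[str],
    phenotype_nodes: tuple[str, ...] = ("reserve", "mmse", "braak", "nft"),
    reserve_node: str = "reserve",
    mmse_node: str = "mmse",
) -> pd.DataFrame:
    """Rank modules by the phenotype content of their Markov blankets.

    Sort key, descending: reserve in blanket; reserve is a direct child;
    number of phenotype nodes in the blanket; MMSE is a direct child; ties
    broken by summed arc frequency between the module and the phenotype
    nodes, then by module name.
    """
    missing = [p for p in phenotype_nodes if p not in dag]
    if missing:
        raise KeyError(f"phenotype nodes missing from graph: {missing}")
    freq = strength.directed
    rows = []
    for module in module_nodes:
        mb = markov_blanket(dag, module)
        children = set(dag.successors(module))
        pheno_strength = sum(
            freq.get((module, p), 0.0) + freq.get((p, module), 0.0)
            for p in phenotype_nodes
        )
        rows.append(
            {
                "module": module,
                "reserve_in_blanket": reserve_node in mb,
                "reserve_is_child": reserve_node in children,
                "n_phenotypes_in_blanket": sum(p in mb for p in phenotype_nodes),
                "mmse_is_child": mmse_node in children,
                "phenotype_arc_strength": pheno_strength,
                "markov_blanket": ",".join(sorted(map(str, mb))),
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=[
            "reserve_in_blanket",
            "reserve_is_child",
            "n_phenotypes_in_blanket",
            "mmse_is_child",
            "phenotype_arc_strength",
            "module",
        ],
        ascending=[False, False, False, False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table
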