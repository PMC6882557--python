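"""Active-module search on metabolite-reaction networks with a
permutation capture null.

Nodes (metabolites) and edges (reactions, annotated with enzyme genes)
are scored from differential-analysis p-values as

    score = -log10(p) + log10(p0)

so a feature exactly at the significance baseline ``p0`` scores zero,
stronger significance scores positive, and weaker negative. Features
absent from the statistics tables receive a small negative
``missing_penalty``. The active module is the connected node set whose
induced subgraph maximizes the summed node and edge scores — found
exactly by enumeration on small graphs and by a multi-restart greedy
local search otherwise.

The capture null shuffles feature identifiers within each omics table
(a permutation: statistics are kept, labels reassigned), re-runs the
module search and records how often a query metabolite is still
captured; that fraction is ``pnull``, and across independent
experiments the evidence aggregates as ``pnull^na * (1-pnull)^nb``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .simulate import MetabolicNetwork

__all__ = [
    "MetabolicNetwork",
    "ScoredNetwork",
    "ModuleResult",
    "CaptureNullResult",
    "score_network",
    "find_module",
    "random_sampling_null",
    "aggregate_capture_p",
]

_EPS = 1e-12


def _pvalue_series(stats_table: pd.DataFrame | pd.Series | None) -> pd.Series:
    if stats_table is None:
        return pd.Series(dtype=float)
    if isinstance(stats_table, pd.Series):
        return stats_table.astype(float)
    return stats_table["p"].astype(float)


@dataclass
class ScoredNetwork:
    network: MetabolicNetwork
    node_score: dict[str, float]
    edge_score: dict[tuple[str, str], float]
    p0: float
    missing_penalty: float


@dataclass
class ModuleResult:
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    total_score: float
    contains: dict[str, bool]


@dataclass
class CaptureNullResult:
    pnull: float
    n_shuffles: int
    capture_flags: tuple[bool, ...]
    seed: int


def _p_to_score(p: float, p0: float) -> float:
    if p <= 0.0:
        warnings.warn("p-value of 0 clipped to the smallest positive float")
        p = float(np.nextafter(0.0, 1.0))
    return float(-np.log10(p) + np.log10(p0))


def score_network(
    network: MetabolicNetwork,
    metab_stats: pd.DataFrame | pd.Series | None,
    gene_stats: pd.DataFrame | pd.Series | None,
    p0: float = 0.05,
    missing_penalty: float = -0.1,
) -> ScoredNetwork:
    """Score nodes from metabolite p-values and edges from the best
    (smallest-p) annotated enzyme gene; unmeasured features get
    ``missing_penalty``."""
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")
    mp = _pvalue_series(metab_stats)
    gp = _pvalue_series(gene_stats)
    node_score = {
        n: _p_to_score(float(mp[n]), p0) if n in mp.index else missing_penalty
        for n in network.graph.nodes
    }
    edge_score = {}
    for u, v, data in network.graph.edges(data=True):
        ps = [float(gp[g]) for g in data["genes"] if g in gp.index]
        score = max(_p_to_score(p, p0) for p in ps) if ps else missing_penalty
        edge_score[_ekey(u, v)] = score
    return ScoredNetwork(network, node_score, edge_score, p0, missing_penalty)


def _ekey(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


def _subset_score(
    nodes: set[str],
    graph: nx.Graph,
    node_score: dict[str, float],
    edge_score: dict[tuple[str, str], float],
) -> float:
    total = sum(node_score[n] for n in nodes)
    for u, v in graph.subgraph(nodes).edges:
        total += edge_score[_ekey(u, v)]
    return total


def _exact_best(
    graph: nx.Graph,
    node_score: dict[str, float],
    edge_score: dict[tuple[str, str], float],
) -> tuple[set[str], float]:
    """Exhaustive optimum over connected induced subgraphs (bitmask scan)."""
    nodes = list(graph.nodes)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj = [0] * n
    edges = []
    for u, v in graph.edges:
        i, j = index[u], index[v]
        adj[i] |= 1 << j
        adj[j] |= 1 << i
        edges.append((1 << i | 1 << j, edge_score[_ekey(u, v)]))
    nscores = [node_score[v] for v in nodes]
    best_mask, best_score = 0, 0.0
    for mask in range(1, 1 << n):
        # connectivity: flood fill from the lowest set bit
        seen = mask & -mask
        frontier = seen
        while frontier:
            nxt = 0
            m = frontier
            while m:
                b = m & -m
                nxt |= adj[b.bit_length() - 1]
                m ^= b
            nxt &= mask & ~seen
            seen |= nxt
            frontier = nxt
        if seen != mask:
            continue
        score = 0.0
        m = mask
        while m:
            b = m & -m
            score += nscores[b.bit_length() - 1]
            m ^= b
        for emask, es in edges:
            if emask & mask == emask:
                score += es
        if score > best_score + _EPS:
            best_mask, best_score = mask, score
    chosen = {nodes[i] for i in range(n) if best_mask >> i & 1}
    return chosen, best_score


def _ascend(
    start: set[str],
    graph: nx.Graph,
    node_score: dict[str, float],
    edge_score: dict[tuple[str, str], float],
) -> tuple[set[str], float]:
    """Steepest-ascent local search with add/remove moves preserving
    connectivity."""
    current = set(start)
    score = _subset_score(current, graph, node_score, edge_score)
    while True:
        best_gain, best_set = 0.0, None
        boundary = {v for u in current for v in graph.neighbors(u)} - current
        for v in boundary:
            gain = node_score[v] + sum(
                edge_score[_ekey(v, u)] for u in graph.neighbors(v) if u in current
            )
            if gain > best_gain + _EPS:
                best_gain, best_set = gain, current | {v}
        for v in current:
            if len(current) == 1:
                continue
            rest = current - {v}
            if not nx.is_connected(graph.subgraph(rest)):
                continue
            gain = -(
                node_score[v]
                + sum(edge_score[_ekey(v, u)] for u in graph.neighbors(v) if u in rest)
            )
            if gain > best_gain + _EPS:
                best_gain, best_set = gain, rest
        if best_set is None:
            return current, score
        current, score = best_set, score + best_gain


def _greedy_best(
    graph: nx.Graph,
    node_score: dict[str, float],
    edge_score: dict[tuple[str, str], float],
) -> tuple[set[str], float]:
    """Multi-restart greedy search with iterated basin hops.

    Restarts from every node, then repeatedly perturbs each local
    optimum by forcing one boundary node in (two on small graphs, where
    edge-pair restarts are also affordable) and re-ascending, accepting
    any improvement. Search effort adapts to component size so small
    graphs are solved essentially exactly while large ones stay fast.
    """
    deep = graph.number_of_nodes() <= 20
    starts = [{v} for v in graph.nodes]
    if deep:
        starts += [{u, v} for u, v in graph.edges]
    best_set: set[str] = set()
    best_score = 0.0
    for start in starts:
        local, score = _ascend(start, graph, node_score, edge_score)
        improved = True
        while improved:
            improved = False
            boundary = {v for u in local for v in graph.neighbors(u)} - local
            hops = [local | {v} for v in boundary]
            if deep:
                for v in boundary:
                    second = (set(graph.neighbors(v)) | boundary) - local - {v}
                    hops += [local | {v, w} for w in second]
            for hop in hops:
                hopped, hop_score = _ascend(hop, graph, node_score, edge_score)
                if hop_score > score + _EPS:
                    local, score = hopped, hop_score
                    improved = True
                    break
        if score > best_score + _EPS:
            best_set, best_score = local, score
    return best_set, best_score


def find_module(
    scored: ScoredNetwork,
    query: str | None = None,
    exact_limit: int = 12,
    seed: int = 0,
) -> ModuleResult:
    """Highest-scoring connected module of a scored network.

    Components with at most ``exact_limit`` nodes are solved by
    exhaustive enumeration (``exact_limit=0`` forces the greedy
    heuristic everywhere); larger components use the greedy local
    search. If no node set scores positive, the module is empty with
    total score 0.
    """
    graph = scored.network.graph
    best_set: set[str] = set()
    best_score = 0.0
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        if len(comp) <= exact_limit:
            nodes, score = _exact_best(sub, scored.node_score, scored.edge_score)
        else:
            nodes, score = _greedy_best(sub, scored.node_score, scored.edge_score)
        if score > best_score + _EPS:
            best_set, best_score = nodes, score
    edges = frozenset(
        _ekey(u, v) for u, v in graph.subgraph(best_set).edges
    )
    contains = {query: query in best_set} if query is not None else {}
    return ModuleResult(
        nodes=frozenset(best_set),
        edges=edges,
        total_score=float(best_score),
        contains=contains,
    )


def _shuffled(
    stats_table: pd.DataFrame | pd.Series | None, rng: np.random.Generator
) -> pd.DataFrame | pd.Series | None:
    """Permute the feature-identifier labels, keeping the statistics."""
    if stats_table is None:
        return None
    out = stats_table.copy()
    out.index = pd.Index(rng.permutation(np.asarray(stats_table.index, dtype=object)))
    return out


def random_sampling_null(
    network: MetabolicNetwork,
    metab_stats: pd.DataFrame | pd.Series | None,
    gene_stats: pd.DataFrame | pd.Series | None,
    query: str,
    n_shuffles: int = 10,
    seed: int = 0,
    p0: float = 0.05,
    missing_penalty: float = -0.1,
    exact_limit: int = 12,
    pseudocount: bool = False,
) -> CaptureNullResult:
    """Capture probability of ``query`` under identifier shuffling.

    Gene and metabolite identifier columns are permuted independently
    (sampling without replacement), the network is rescored and the
    module search re-run; ``pnull`` is the fraction of shuffles that
    still capture the query. ``pseudocount=True`` uses the
    (captures+1)/(R+1) estimator instead of the plain fraction.
    """
    if query not in network.graph.nodes:
        raise ValueError(f"query {query!r} not a network node")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be positive")
    flags = []
    for r in range(n_shuffles):
        rng = np.random.default_rng([seed, r])
        scored = score_network(
            network,
            _shuffled(metab_stats, rng),
            _shuffled(gene_stats, rng),
            p0=p0,
            missing_penalty=missing_penalty,
        )
        module = find_module(scored, query=query, exact_limit=exact_limit, seed=seed)
        flags.append(bool(module.contains[query]))
    captures = sum(flags)
    pnull = (
        (captures + 1) / (n_shuffles + 1) if pseudocount else captures / n_shuffles
    )
    return CaptureNullResult(
        pnull=float(pnull),
        n_shuffles=n_shuffles,
        capture_flags=tuple(flags),
        seed=seed,
    )


def aggregate_capture_p(pnull: float, na: int, nb: int) -> float:
    """Aggregate capture evidence across experiments:
    ``p = pnull^na * (1 - pnull)^nb`` (0^0 = 1).

    ``na`` experiments captured the query, ``nb`` did not. This is a
    likelihood-style product, reported exactly as defined rather than a
    calibrated tail probability.
    """
    if not 0.0 <= pnull <= 1.0:
        raise ValueError("pnull must lie in [0, 1]")
    if na < 0 or nb < 0:
        raise ValueError("na and nb must be non-negative")
    return float(pnull**na * (1.0 - pnull) ** nb)
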