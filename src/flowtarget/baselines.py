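"""Comparison rankers: centralities, random walk with restart, t-test.

All rankers consume the same weighted network / candidate set / disease set
as the flow method and return a total order over the candidates (score
descending, lexicographic tie break), so that evaluation compares like with
like. Shortest-path centralities convert capacity to distance as d = 1/w;
zero-capacity arcs are unusable.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

from .expression import ExpressionMatrix, ttest_statistic
from .network import PPI, REGULATORY, WeightedNetwork

__all__ = [
    "degree_rank",
    "entropy_rank",
    "betweenness_rank",
    "closeness_rank",
    "rwr_rank",
    "ttest_rank",
    "randomize_directions",
]


def _order(scores: dict[str, float], candidates: set[str]) -> list[str]:
    return sorted(candidates, key=lambda c: (-scores.get(c, 0.0), c))


def _link_degrees(net: WeightedNetwork) -> dict[str, int]:
    """Incident links per node: a PPI pair counts once, a directed arc once."""
    deg: dict[str, int] = {v: 0 for v in net.graph.nodes}
    seen_ppi: set[tuple[str, str]] = set()
    for u, v, d in net.graph.edges(data=True):
        if d["origin"] == PPI:
            key = tuple(sorted((u, v)))
            if key in seen_ppi:
                continue
            seen_ppi.add(key)
        deg[u] += 1
        deg[v] += 1
    return deg


def _undirected_neighbors(net: WeightedNetwork) -> dict[str, set[str]]:
    nbrs: dict[str, set[str]] = {v: set() for v in net.graph.nodes}
    for u, v in net.graph.edges():
        nbrs[u].add(v)
        nbrs[v].add(u)
    return nbrs


def degree_rank(net: WeightedNetwork, candidates: set[str]) -> list[str]:
    """Rank by number of incident links, hubs first."""
    deg = _link_degrees(net)
    return _order({k: float(v) for k, v in deg.items()}, candidates)


def entropy_rank(net: WeightedNetwork, candidates: set[str]) -> list[str]:
    """Rank by the Shannon entropy of each node's neighbor-degree distribution.

    For node i with neighbors N(i), p_j = deg(j) / sum_{l in N(i)} deg(l) and
    H_i = -sum p_j log2 p_j. Isolated nodes score 0.
    """
    deg = _link_degrees(net)
    nbrs = _undirected_neighbors(net)
    scores: dict[str, float] = {}
    for node in net.graph.nodes:
        ds = [deg[j] for j in nbrs[node] if deg[j] > 0]
        total = sum(ds)
        if total == 0:
            scores[node] = 0.0
            continue
        scores[node] = -sum(
            (d / total) * math.log2(d / total) for d in ds
        )
    return _order(scores, candidates)


def _distance_graph(net: WeightedNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(net.graph.nodes)
    for u, v, d in net.graph.edges(data=True):
        w = d["capacity"]
        if w > 0.0:
            g.add_edge(u, v, distance=1.0 / w, capacity=w)
    return g


def betweenness_rank(net: WeightedNetwork, candidates: set[str]) -> list[str]:
    """Rank by shortest-path betweenness centrality, distances 1/w."""
    g = _distance_graph(net)
    scores = nx.betweenness_centrality(g, weight="distance", normalized=True)
    return _order(scores, candidates)


def closeness_rank(net: WeightedNetwork, candidates: set[str]) -> list[str]:
    """Rank by outgoing closeness (n_reachable - 1) / sum of distances."""
    g = _distance_graph(net)
    # networkx closeness uses incoming distance; reverse for "from this node"
    scores = nx.closeness_centrality(
        g.reverse(copy=False), distance="distance", wf_improved=False
    )
    return _order(scores, candidates)


def rwr_scores(
    net: WeightedNetwork,
    candidate: str,
    disease: set[str],
    alpha: float = 0.3,
) -> float:
    """Restart-walk proximity of one candidate to the disease genes.

    The walker follows capacity-proportional out-arcs and restarts at the
    candidate with probability ``alpha`` each step (dangling mass returns to
    the candidate); the score is the stationary probability summed over
    disease genes.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    g = _distance_graph(net)
    if candidate not in g:
        g.add_node(candidate)
    stationary = nx.pagerank(
        g,
        alpha=1.0 - alpha,
        personalization={candidate: 1.0},
        dangling={candidate: 1.0},
        weight="capacity",
        max_iter=10000,
        tol=1e-12,
    )
    return float(sum(stationary.get(d, 0.0) for d in disease))


def rwr_rank(
    net: WeightedNetwork,
    candidates: set[str],
    disease: set[str],
    alpha: float = 0.3,
) -> list[str]:
    """Rank candidates by restart-walk proximity to the disease genes."""
    scores = {c: rwr_scores(net, c, disease, alpha=alpha) for c in candidates}
    return _order(scores, candidates)


def ttest_rank(matrix: ExpressionMatrix, candidates: set[str]) -> list[str]:
    """Rank by |Welch t| of cancer-vs-normal differential expression."""
    scores = {}
    for c in candidates:
        if c in matrix.values.index:
            scores[c] = abs(ttest_statistic(matrix, c))
    return _order(scores, candidates)


def randomize_directions(net: WeightedNetwork, seed: int) -> WeightedNetwork:
    """Collapse every bidirectional PPI arc pair to one random direction.

    Each PPI pair becomes a single directed arc (fair coin, seeded);
    regulatory arcs and all capacities are untouched. Turns the partially
    directed interactome into a fully directed one.
    """
    rng = np.random.default_rng(seed)
    out = WeightedNetwork()
    out.graph.add_nodes_from(net.graph.nodes)
    for u, v, d in net.graph.edges(data=True):
        if d["origin"] == REGULATORY:
            out.add_arc(u, v, d["capacity"], REGULATORY)
    for u, v in net.ppi_pairs():
        cap = net.graph[u][v]["capacity"] if net.graph.has_edge(u, v) else net.graph[v][u]["capacity"]
        if rng.integers(0, 2) == 0:
            out.add_arc(u, v, cap, PPI)
        else:
            out.add_arc(v, u, cap, PPI)
    return out


def log_trend_fit(ranks: list[int], values: list[float]) -> tuple[float, float]:
    """Least-squares fit of y = a·ln(x) + b over (rank, value) points."""
    if len(ranks) != len(values):
        raise ValueError("ranks and values must have equal length")
    if len(ranks) < 2:
        raise ValueError("need at least 2 points")
    if any(r < 1 for r in ranks):
        raise ValueError("ranks must be >= 1")
    x = np.log(np.asarray(ranks, dtype=float))
    a, b = np.polyfit(x, np.asarray(values, dtype=float), 1)
    return float(a), float(b)
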