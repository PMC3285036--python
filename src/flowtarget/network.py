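"""Construction of the expression-weighted, partially directed interactome.

Protein–protein interactions are bidirectional and expand to two antiparallel
arcs of equal capacity; transcription-factor → gene regulation keeps its
orientation. Every arc gets the co-expression capacity

    w_ij = |R_ij| * (|E_ci - E_ni| + |E_cj - E_nj|)

where R_ij is the Pearson correlation of the two genes over cancer samples
and E_c/E_n are the per-condition mean log2 ratios. A zero weight means the
pair is uncorrelated or not differentially expressed and carries no flow.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx

from .expression import CANCER, NORMAL, ExpressionMatrix, condition_mean, pearson_cancer

logger = logging.getLogger(__name__)

PPI = "ppi"
REGULATORY = "regulatory"


@dataclass(frozen=True)
class InteractionRecord:
    """One raw interaction: undirected PPI or directed TF→gene regulation."""

    a: str
    b: str
    directed: bool = False
    source: str = ""

    def key(self) -> tuple:
        if self.directed:
            return ("d", self.a, self.b)
        u, v = sorted((self.a, self.b))
        return ("u", u, v)


@dataclass
class WeightedNetwork:
    """Capacity-weighted directed multigraph over gene ids.

    ``graph`` is a :class:`networkx.DiGraph`; each arc carries attributes
    ``capacity`` (>= 0, finite) and ``origin`` (``"ppi"`` or
    ``"regulatory"``). PPI records contribute both (u, v) and (v, u) with
    equal capacity.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def arcs(self) -> list[tuple[str, str, float, str]]:
        return [
            (u, v, d["capacity"], d["origin"])
            for u, v, d in self.graph.edges(data=True)
        ]

    def capacity(self, u: str, v: str) -> float:
        return self.graph[u][v]["capacity"]

    def add_arc(self, u: str, v: str, capacity: float, origin: str) -> None:
        if u == v:
            raise ValueError(f"self-loop arc {u!r}")
        if not math.isfinite(capacity) or capacity < 0:
            raise ValueError(f"capacity must be finite and >= 0, got {capacity}")
        # identical-direction duplicates collapse; capacity is identical by
        # construction so keeping the first is safe
        if not self.graph.has_edge(u, v):
            self.graph.add_edge(u, v, capacity=float(capacity), origin=origin)

    def total_capacity(self) -> float:
        return sum(d["capacity"] for _, _, d in self.graph.edges(data=True))

    def ppi_pairs(self) -> list[tuple[str, str]]:
        """Unordered PPI pairs (u < v) present as antiparallel arc pairs."""
        pairs = set()
        for u, v, d in self.graph.edges(data=True):
            if d["origin"] == PPI:
                pairs.add(tuple(sorted((u, v))))
        return sorted(pairs)


def map_and_deduplicate(
    records: list[InteractionRecord], id_map: dict[str, str] | None = None
) -> list[InteractionRecord]:
    """Canonicalize endpoints through the synonym map and drop duplicates.

    Undirected duplicates collapse regardless of endpoint order; directed
    duplicates collapse only with matching orientation. A directed and an
    undirected record over the same pair are both kept (they contribute
    different arcs). Self-loops after mapping are dropped.
    """
    id_map = id_map or {}
    seen: set[tuple] = set()
    out: list[InteractionRecord] = []
    n_dupe = n_loop = 0
    for rec in records:
        a = id_map.get(rec.a, rec.a)
        b = id_map.get(rec.b, rec.b)
        mapped = InteractionRecord(a, b, rec.directed, rec.source)
        if a == b:
            n_loop += 1
            continue
        k = mapped.key()
        if k in seen:
            n_dupe += 1
            continue
        seen.add(k)
        out.append(mapped)
    if n_dupe or n_loop:
        logger.info(
            "deduplication dropped %d duplicate and %d self-loop records", n_dupe, n_loop
        )
    return out


def edge_capacity(
    r_ij: float, e_ci: float, e_ni: float, e_cj: float, e_nj: float
) -> float:
    """Co-expression edge capacity |R| * (|ΔE_i| + |ΔE_j|)."""
    vals = (r_ij, e_ci, e_ni, e_cj, e_nj)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError(f"non-finite input to edge_capacity: {vals}")
    return abs(r_ij) * (abs(e_ci - e_ni) + abs(e_cj - e_nj))


def build_weighted_network(
    records: list[InteractionRecord], matrix: ExpressionMatrix
) -> WeightedNetwork:
    """Assign capacities to deduplicated interaction records.

    Records whose endpoints are both present in the (imputed) matrix get the
    co-expression capacity; others are dropped with a logged count. PPI
    records expand to two antiparallel arcs; regulatory records keep one.
    """
    if not records:
        raise ValueError("no interaction records")
    if matrix.has_missing():
        raise ValueError("expression matrix must be imputed before weighting")
    genes = set(matrix.gene_ids)
    net = WeightedNetwork()
    # cache per-gene differential expression
    delta: dict[str, float] = {}

    def dexpr(g: str) -> float:
        if g not in delta:
            delta[g] = abs(
                condition_mean(matrix, g, CANCER) - condition_mean(matrix, g, NORMAL)
            )
        return delta[g]

    n_dropped = 0
    for rec in records:
        if rec.a not in genes or rec.b not in genes:
            n_dropped += 1
            continue
        r = pearson_cancer(matrix, rec.a, rec.b)
        w = abs(r) * (dexpr(rec.a) + dexpr(rec.b))
        if rec.directed:
            net.add_arc(rec.a, rec.b, w, REGULATORY)
        else:
            net.add_arc(rec.a, rec.b, w, PPI)
            net.add_arc(rec.b, rec.a, w, PPI)
    if n_dropped:
        logger.info("dropped %d records lacking expression for an endpoint", n_dropped)
    return net
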