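"""Per-candidate maximum flow on the augmented interactome.

For a chosen candidate protein the weighted network is augmented with a
dummy source S (one arc S→candidate) and a dummy sink T (one arc from every
disease gene that is not itself a candidate), both at a big-M capacity
exceeding the total finite capacity. The maximum S→T flow is the candidate's
score; it is computed with a push-relabel algorithm whose node heights are
initialized to the BFS hop distance to T.

Per-arc flows of a maximum flow are not unique in general; all iteration
here follows a fixed lexicographic node order so that repeated runs are
bit-identical (the "canonical" solution). The flow *value* is of course
solver-independent.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .network import WeightedNetwork

SOURCE = "S"
SINK = "T"


@dataclass
class FlowNetwork:
    """Augmented flow network for one candidate.

    ``arcs`` maps (u, v) -> capacity; dummy arcs carry ``big_m``. ``nodes``
    is ordered deterministically: S, T, then base nodes sorted.
    """

    candidate: str
    disease_set: frozenset[str]
    candidate_set: frozenset[str]
    big_m: float
    arcs: dict[tuple[str, str], float]
    nodes: list[str]
    disconnected_candidate: bool = False

    def out_neighbors(self, u: str) -> list[str]:
        return sorted(v for (a, v) in self.arcs if a == u)

    def in_degree(self, v: str) -> int:
        return sum(1 for (_, b) in self.arcs if b == v)


@dataclass
class FlowResult:
    """Canonical maximum-flow solution for one candidate."""

    candidate: str
    value: float
    arc_flows: dict[tuple[str, str], float]
    heights: dict[str, int]
    pushed_steps: list[tuple[str, float, str]] = field(default_factory=list)

    def arc_flow(self, u: str, v: str) -> float:
        if (u, v) not in self.arc_flows:
            raise KeyError(f"no arc ({u!r}, {v!r})")
        return self.arc_flows[(u, v)]


def build_flow_network(
    net: WeightedNetwork,
    candidate: str,
    disease_set: set[str],
    candidate_set: set[str] | None = None,
) -> FlowNetwork:
    """Attach dummy source/sink arcs around ``candidate``.

    Disease genes that are themselves candidate proteins get no arc to the
    sink (they may only receive flow from the source side). A candidate
    absent from the network yields a valid instance whose max flow is 0,
    flagged ``disconnected_candidate``.
    """
    if not disease_set:
        raise ValueError("empty disease set")
    candidate_set = set(candidate_set) if candidate_set is not None else {candidate}
    if candidate not in candidate_set:
        raise ValueError("candidate must be a member of candidate_set")
    base_nodes = set(net.graph.nodes)
    if SOURCE in base_nodes or SINK in base_nodes:
        raise ValueError(f"reserved node ids {SOURCE!r}/{SINK!r} present in network")

    arcs: dict[tuple[str, str], float] = {
        (u, v): d["capacity"] for u, v, d in net.graph.edges(data=True)
    }
    big_m = net.total_capacity() + 1.0
    disconnected = candidate not in base_nodes
    arcs[(SOURCE, candidate)] = big_m
    for g in sorted(disease_set):
        if g in candidate_set:
            continue
        if g in base_nodes or g == candidate:
            arcs[(g, SINK)] = big_m
    nodes = [SOURCE, SINK] + sorted(base_nodes | {candidate})
    return FlowNetwork(
        candidate=candidate,
        disease_set=frozenset(disease_set),
        candidate_set=frozenset(candidate_set),
        big_m=big_m,
        arcs=arcs,
        nodes=nodes,
        disconnected_candidate=disconnected,
    )


def bfs_heights(fn: FlowNetwork) -> dict[str, int]:
    """Hop distance from every node to the sink along arc directions.

    T gets 0; nodes that cannot reach T get the sentinel ``len(nodes)``.
    """
    n = len(fn.nodes)
    preds: dict[str, list[str]] = {v: [] for v in fn.nodes}
    for (u, v) in fn.arcs:
        preds[v].append(u)
    heights = {v: n for v in fn.nodes}
    heights[SINK] = 0
    queue = deque([SINK])
    while queue:
        v = queue.popleft()
        for u in sorted(preds[v]):
            if heights[u] == n:
                heights[u] = heights[v] + 1
                queue.append(u)
    return heights


def _canonical_step_log(
    fn: FlowNetwork, flows: dict[tuple[str, str], float], tol: float = 1e-12
) -> list[tuple[str, float, str]]:
    """Arcs carrying positive flow, ordered source-outward.

    Ordering is BFS distance of the pushing node from S (over flow-carrying
    arcs), then lexicographic on (pusher, receiver); this renders the
    solution as the step table 'push node, flow, received node'.
    """
    carrying = {(u, v): f for (u, v), f in flows.items() if f > tol}
    dist = {SOURCE: 0}
    queue = deque([SOURCE])
    while queue:
        u = queue.popleft()
        for (a, v) in sorted(carrying):
            if a == u and v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return [
        (u, f, v)
        for (u, v), f in sorted(
            carrying.items(), key=lambda kv: (dist.get(kv[0][0], len(fn.nodes)), kv[0])
        )
    ]


def max_flow_push_relabel(fn: FlowNetwork) -> FlowResult:
    """Maximum S→T flow by push-relabel with BFS-initialized heights.

    Highest-label active-node selection with FIFO tie-break on insertion
    order; heights are re-derived by a global BFS relabel every |V| relabel
    operations. Zero-capacity arcs are present but never admissible.
    """
    nodes = fn.nodes
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}

    # residual graph: cap[u][v] = residual capacity; reverse arcs start at 0
    cap: dict[str, dict[str, float]] = {v: {} for v in nodes}
    for (u, v), c in fn.arcs.items():
        cap[u][v] = cap[u].get(v, 0.0) + c
        cap[v].setdefault(u, 0.0)
    adj = {u: sorted(cap[u]) for u in nodes}

    height = bfs_heights(fn)
    height[SOURCE] = n
    excess = {v: 0.0 for v in nodes}

    def push(u: str, v: str, amount: float) -> None:
        cap[u][v] -= amount
        cap[v][u] += amount
        excess[u] -= amount
        excess[v] += amount

    # saturate the source's out-arcs
    for v in adj[SOURCE]:
        c = cap[SOURCE][v]
        if c > 0.0:
            push(SOURCE, v, c)

    def active_nodes() -> list[str]:
        return [v for v in nodes if v not in (SOURCE, SINK) and excess[v] > 1e-12]

    relabel_count = 0
    work = active_nodes()
    while work:
        # highest label first; FIFO (insertion order == node order) tie-break
        work.sort(key=lambda v: (-height[v], index[v]))
        u = work[0]
        pushed = False
        for v in adj[u]:
            if cap[u][v] > 1e-12 and height[u] == height[v] + 1:
                amount = min(excess[u], cap[u][v])
                push(u, v, amount)
                pushed = True
                if excess[u] <= 1e-12:
                    break
        if not pushed:
            # relabel: one above the lowest admissible-capacity neighbor
            candidates = [height[v] for v in adj[u] if cap[u][v] > 1e-12]
            if not candidates:
                excess[u] = 0.0  # numerically stranded dust
            else:
                height[u] = min(candidates) + 1
                relabel_count += 1
                if relabel_count % n == 0:
                    _global_relabel(nodes, cap, height, n)
        work = active_nodes()

    value = excess[SINK]
    # per-arc flows from the residual: net(u,v) = c(u,v) - residual(u,v);
    # for antiparallel original pairs the positive side carries the net flow
    flows: dict[tuple[str, str], float] = {}
    for (u, v), c in fn.arcs.items():
        net_flow = c - cap[u][v]
        flows[(u, v)] = net_flow if net_flow > 1e-12 else 0.0
    return FlowResult(
        candidate=fn.candidate,
        value=float(value),
        arc_flows=flows,
        heights=dict(height),
        pushed_steps=_canonical_step_log(fn, flows),
    )


def _global_relabel(
    nodes: list[str], cap: dict[str, dict[str, float]], height: dict[str, int], n: int
) -> None:
    """Recompute heights as residual-graph BFS distance to the sink."""
    dist = {v: None for v in nodes}
    dist[SINK] = 0
    queue = deque([SINK])
    while queue:
        v = queue.popleft()
        for u in sorted(cap[v]):  # u with residual arc u->v
            if dist[u] is None and cap[u].get(v, 0.0) > 1e-12:
                dist[u] = dist[v] + 1
                queue.append(u)
    for v in nodes:
        if v == SOURCE:
            continue
        if dist[v] is not None:
            height[v] = dist[v]
        elif height[v] < n:
            height[v] = n


def arc_flow(fr: FlowResult, u: str, v: str) -> float:
    """Flow on arc (u, v) in the canonical solution."""
    return fr.arc_flow(u, v)


def edmonds_karp_oracle(fn: FlowNetwork) -> float:
    """Independent maximum-flow value by shortest augmenting paths.

    Test oracle only — shares no code with the push-relabel solver.
    """
    cap: dict[str, dict[str, float]] = {v: {} for v in fn.nodes}
    for (u, v), c in fn.arcs.items():
        cap[u][v] = cap[u].get(v, 0.0) + c
        cap[v].setdefault(u, 0.0)
    total = 0.0
    while True:
        parent = {SOURCE: None}
        queue = deque([SOURCE])
        while queue and SINK not in parent:
            u = queue.popleft()
            for v in sorted(cap[u]):
                if v not in parent and cap[u][v] > 1e-12:
                    parent[v] = u
                    queue.append(v)
        if SINK not in parent:
            return total
        bottleneck = float("inf")
        v = SINK
        while parent[v] is not None:
            u = parent[v]
            bottleneck = min(bottleneck, cap[u][v])
            v = u
        v = SINK
        while parent[v] is not None:
            u = parent[v]
            cap[u][v] -= bottleneck
            cap[v][u] += bottleneck
            v = u
        total += bottleneck
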