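"""Affected-genes score: how widely a candidate's flow spreads.

Inhibiting a candidate protein perturbs every gene its flow passes through.
For each non-dummy node i with positive inflow in the canonical maximum-flow
solution, the affected ratio is

    P_i = F_i / K_i

with K_i the node's in-degree in the augmented network and F_i the number of
its incoming arcs that actually carry flow; the dummy source arc counts for
the candidate, the dummy nodes themselves are excluded. The total
AG = sum of the P_i is the candidate's off-target spread score. Because a
maximum flow's arc decomposition is not unique, AG is defined on the
canonical (deterministically ordered) solution.
"""

from __future__ import annotations

from dataclasses import dataclass

from .flow import SINK, SOURCE, FlowNetwork, FlowResult

_TOL = 1e-12


@dataclass
class AffectedScore:
    candidate: str
    per_node: dict[str, float]
    total: float


def _incoming(fn: FlowNetwork, node: str) -> list[tuple[str, str]]:
    return [(u, v) for (u, v) in fn.arcs if v == node]


def affected_ratio(node: str, fr: FlowResult, fn: FlowNetwork) -> float:
    """F_i / K_i for one flow-receiving node."""
    if node in (SOURCE, SINK):
        raise ValueError("affected ratio is defined for gene nodes only")
    incoming = _incoming(fn, node)
    inflow = sum(fr.arc_flows.get(arc, 0.0) for arc in incoming)
    if inflow <= _TOL:
        raise ValueError(f"node {node!r} receives no flow")
    k = len(incoming)
    f = sum(1 for arc in incoming if fr.arc_flows.get(arc, 0.0) > _TOL)
    return f / k


def affected_genes_total(fr: FlowResult, fn: FlowNetwork) -> AffectedScore:
    """Sum affected ratios over all non-dummy nodes with positive inflow."""
    per_node: dict[str, float] = {}
    receiving = {v for (u, v), f in fr.arc_flows.items() if f > _TOL and v != SINK}
    for node in sorted(receiving):
        per_node[node] = affected_ratio(node, fr, fn)
    return AffectedScore(
        candidate=fr.candidate, per_node=per_node, total=sum(per_node.values())
    )
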