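"""Candidate ranking by maximum flow and the top-5% selection threshold.

Each candidate protein is scored by the maximum flow it can deliver to the
disease genes; candidates are sorted by flow (descending, lexicographic tie
break) and the top set is cut at the upper 5% tail of a normal fitted to the
empirical flow distribution (central-limit appeal): mean + z_0.95 · sd.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .flow import build_flow_network, max_flow_push_relabel
from .network import WeightedNetwork
from .side_effects import affected_genes_total

logger = logging.getLogger(__name__)


@dataclass
class RankingRow:
    candidate: str
    flow: float
    affected: float
    rank: int
    disconnected: bool = False


@dataclass
class RankingTable:
    rows: list[RankingRow]
    threshold: float | None = None

    @property
    def selected(self) -> list[str]:
        if self.threshold is None:
            return []
        return [r.candidate for r in self.rows if r.flow >= self.threshold]

    def order(self) -> list[str]:
        return [r.candidate for r in self.rows]


def rank_candidates(
    net: WeightedNetwork,
    candidates: set[str],
    disease: set[str],
    tail: float = 0.05,
    with_threshold: bool = True,
) -> RankingTable:
    """Score every candidate by max flow (fresh augmented network each) and
    the affected-genes score from the same canonical run."""
    if not candidates:
        raise ValueError("empty candidate set")
    if not disease:
        raise ValueError("empty disease set")
    rows = []
    for cand in sorted(candidates):
        fn = build_flow_network(net, cand, disease, candidate_set=candidates)
        if fn.disconnected_candidate:
            logger.warning("candidate %s absent from network; flow 0", cand)
        fr = max_flow_push_relabel(fn)
        ag = affected_genes_total(fr, fn)
        rows.append(
            RankingRow(
                candidate=cand,
                flow=fr.value,
                affected=ag.total,
                rank=0,
                disconnected=fn.disconnected_candidate,
            )
        )
    rows.sort(key=lambda r: (-r.flow, r.candidate))
    for i, r in enumerate(rows, start=1):
        r.rank = i
    threshold = None
    if with_threshold and len(rows) >= 2:
        threshold = top_flow_threshold([r.flow for r in rows], tail=tail)
    return RankingTable(rows=rows, threshold=threshold)


def top_flow_threshold(flows: list[float], tail: float = 0.05) -> float:
    """Upper-tail cutoff mean + z_(1-tail) · sd under a fitted normal.

    Uses the sample (n-1) standard deviation; with the default 5% tail the
    multiplier is z_0.95 ≈ 1.6449.
    """
    if len(flows) < 2:
        raise ValueError("need at least 2 flow values")
    if not 0.0 < tail < 1.0:
        raise ValueError("tail must lie in (0, 1)")
    arr = np.asarray(flows, dtype=float)
    z = float(_stats.norm.ppf(1.0 - tail))
    return float(arr.mean() + z * arr.std(ddof=1))
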