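"""End-to-end run: preprocess → weight network → rank → (optional) evaluate."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as ftio
from .baselines import (
    betweenness_rank,
    closeness_rank,
    degree_rank,
    entropy_rank,
    rwr_rank,
    ttest_rank,
)
from .evaluation import EvalReport, precision_recall, topk_average_position
from .expression import filter_genes_by_missingness, knn_impute
from .network import build_weighted_network, map_and_deduplicate
from .ranking import RankingTable, rank_candidates

logger = logging.getLogger(__name__)

BASELINES = {
    "degree": degree_rank,
    "entropy": entropy_rank,
    "betweenness": betweenness_rank,
    "closeness": closeness_rank,
}


@dataclass
class RunConfig:
    matrix_path: str
    condition_path: str
    edges_path: str
    candidates_path: str
    disease_path: str
    id_map_path: str | None = None
    knn_k: int = 10
    missing_threshold: float = 0.2
    tail: float = 0.05
    rwr_alpha: float = 0.3
    seed: int = 0
    output_dir: str = "flowtarget_out"
    methods: list[str] = field(default_factory=list)  # baselines to evaluate
    truth_path: str | None = None  # known targets for evaluation

    def __post_init__(self) -> None:
        for name in ("missing_threshold", "tail", "rwr_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


def run_pipeline(config: RunConfig) -> tuple[RankingTable, list[EvalReport]]:
    """Execute the full prioritization and write all output files.

    Outputs: ``ranking.tsv``, ``network.tsv``, optional ``evaluation.tsv``
    and a machine-readable ``run_summary.json`` in ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrix = ftio.read_expression(config.matrix_path, config.condition_path)
    n_raw = len(matrix.gene_ids)
    matrix = filter_genes_by_missingness(matrix, config.missing_threshold)
    n_kept = len(matrix.gene_ids)
    matrix = knn_impute(matrix, k=config.knn_k)
    logger.info("[preprocess] kept %d/%d genes after missingness filter", n_kept, n_raw)

    records = ftio.read_edges(config.edges_path)
    id_map = ftio.read_id_map(config.id_map_path) if config.id_map_path else {}
    records = map_and_deduplicate(records, id_map)
    net = build_weighted_network(records, matrix)
    ftio.write_network(net, out / "network.tsv")
    logger.info(
        "[network] %d nodes, %d arcs", len(net.nodes), net.graph.number_of_edges()
    )

    candidates = ftio.read_gene_list(config.candidates_path)
    disease = ftio.read_gene_list(config.disease_path)
    table = rank_candidates(net, candidates, disease, tail=config.tail)
    ftio.write_ranking(table, out / "ranking.tsv")
    n_disconnected = sum(r.disconnected for r in table.rows)
    logger.info("[rank] %d candidates, %d disconnected", len(table.rows), n_disconnected)

    reports: list[EvalReport] = []
    if config.truth_path:
        truth = ftio.read_gene_list(config.truth_path)
        orders: dict[str, list[str]] = {"flow": table.order()}
        for name in config.methods:
            if name in BASELINES:
                orders[name] = BASELINES[name](net, candidates)
            elif name == "rwr":
                orders[name] = rwr_rank(net, candidates, disease, alpha=config.rwr_alpha)
            elif name == "ttest":
                orders[name] = ttest_rank(matrix, candidates)
            elif name != "flow":
                raise ValueError(f"unknown method {name!r}")
        for name, order in orders.items():
            rep = precision_recall(order, truth & set(order), method=name)
            rep.topk = topk_average_position(order, truth & set(order), method=name).topk
            reports.append(rep)
        ftio.write_eval_report(reports, out / "evaluation.tsv")

    summary = {
        "genes_input": n_raw,
        "genes_kept": n_kept,
        "edges_input": len(records),
        "network_nodes": len(net.nodes),
        "network_arcs": net.graph.number_of_edges(),
        "candidates": len(table.rows),
        "disconnected_candidates": n_disconnected,
        "threshold": table.threshold,
        "selected": table.selected,
        "seed": config.seed,
    }
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return table, reports
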