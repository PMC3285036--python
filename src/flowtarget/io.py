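"""TSV readers and writers for all pipeline inputs and outputs.

Dialects
--------
* Expression matrix: header row of sample ids, first column gene id, missing
  entries empty or ``NA``.
* Condition map: ``sample<TAB>cancer|normal``.
* Edge list: ``u<TAB>v<TAB>type[<TAB>source]`` with type ``ppi`` or
  ``regulatory`` (case-insensitive); ``#`` lines are comments.
* Gene list: one id per line; id map: ``alias<TAB>canonical``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import CANCER, NORMAL, ExpressionMatrix
from .network import PPI, REGULATORY, InteractionRecord, WeightedNetwork
from .ranking import RankingTable
from .side_effects import AffectedScore
from .evaluation import EvalReport
from .flow import FlowResult
from .simulate import SyntheticDataset

logger = logging.getLogger(__name__)

_MISSING = {"", "NA", "nan", "NaN"}


def _lines(path: str | Path) -> list[tuple[int, str]]:
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            out.append((lineno, line))
    return out


def read_condition_map(path: str | Path) -> dict[str, str]:
    cond: dict[str, str] = {}
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
        sample, label = fields
        label = label.strip().lower()
        if label not in (CANCER, NORMAL):
            raise ValueError(f"{path}:{lineno}: unknown condition {label!r}")
        cond[sample.strip()] = label
    return cond


def read_expression(path: str | Path, condition_path: str | Path) -> ExpressionMatrix:
    """Parse the matrix TSV and attach the sample→condition map."""
    rows = _lines(path)
    if not rows:
        raise ValueError(f"{path}: empty expression file")
    header = rows[0][1].split("\t")
    samples = [s.strip() for s in header[1:]]
    n_fields = len(header)
    gene_ids: list[str] = []
    data: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in rows[1:]:
        fields = line.split("\t")
        if len(fields) != n_fields:
            raise ValueError(
                f"{path}:{lineno}: expected {n_fields} fields, got {len(fields)}"
            )
        gene = fields[0].strip()
        if gene in seen:
            raise ValueError(f"{path}:{lineno}: duplicate gene id {gene!r}")
        seen.add(gene)
        gene_ids.append(gene)
        data.append(
            [np.nan if f.strip() in _MISSING else float(f) for f in fields[1:]]
        )
    condition = read_condition_map(condition_path)
    unlabeled = [s for s in samples if s not in condition]
    if unlabeled:
        raise ValueError(f"samples without condition: {unlabeled[:5]}")
    frame = pd.DataFrame(data, index=gene_ids, columns=samples, dtype=float)
    logger.info("read %d genes x %d samples from %s", *frame.shape, path)
    return ExpressionMatrix(frame, {s: condition[s] for s in samples})


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", na_rep="NA", index_label="gene")


def write_condition_map(condition: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, label in condition.items():
            fh.write(f"{sample}\t{label}\n")


def read_edges(path: str | Path) -> list[InteractionRecord]:
    records = []
    for lineno, line in _lines(path):
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) not in (3, 4):
            raise ValueError(f"{path}:{lineno}: expected 3 or 4 fields")
        u, v, kind = fields[:3]
        source = fields[3] if len(fields) == 4 else ""
        kind = kind.lower()
        if kind not in (PPI, REGULATORY):
            raise ValueError(f"{path}:{lineno}: unknown edge type {kind!r}")
        records.append(
            InteractionRecord(u, v, directed=(kind == REGULATORY), source=source)
        )
    return records


def write_edges(records: list[InteractionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# u\tv\ttype\tsource\n")
        for r in records:
            kind = REGULATORY if r.directed else PPI
            fh.write(f"{r.a}\t{r.b}\t{kind}\t{r.source}\n")


def read_gene_list(path: str | Path) -> set[str]:
    genes: set[str] = set()
    n_dupe = 0
    for _, line in _lines(path):
        g = line.strip()
        if g in genes:
            n_dupe += 1
        genes.add(g)
    if n_dupe:
        logger.warning("%s: %d duplicate gene entries collapsed", path, n_dupe)
    if not genes:
        raise ValueError(f"{path}: empty gene list")
    return genes


def write_gene_list(genes: set[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_id_map(path: str | Path) -> dict[str, str]:
    id_map: dict[str, str] = {}
    for lineno, line in _lines(path):
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 fields")
        id_map[fields[0]] = fields[1]
    return id_map


def write_network(net: WeightedNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# u\tv\tcapacity\torigin\n")
        for u, v, cap, origin in sorted(net.arcs()):
            fh.write(f"{u}\t{v}\t{cap:.10g}\t{origin}\n")


def read_network(path: str | Path) -> WeightedNetwork:
    net = WeightedNetwork()
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 fields")
        u, v, cap, origin = fields
        net.add_arc(u.strip(), v.strip(), float(cap), origin.strip())
    return net


def write_ranking(table: RankingTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("candidate\tflow\taffected_genes\trank\tselected\n")
        sel = set(table.selected)
        for r in table.rows:
            fh.write(
                f"{r.candidate}\t{r.flow:.10g}\t{r.affected:.10g}\t{r.rank}\t"
                f"{'yes' if r.candidate in sel else 'no'}\n"
            )
        if table.threshold is not None:
            fh.write(f"# threshold\t{table.threshold:.10g}\n")


def write_flow_result(fr: FlowResult, capacities: dict, path: str | Path) -> None:
    """Per-arc flows plus the step log mirroring the worked-example table."""
    with open(path, "w") as fh:
        fh.write("u\tv\tflow\tcapacity\n")
        for (u, v), f in sorted(fr.arc_flows.items()):
            fh.write(f"{u}\t{v}\t{f:.10g}\t{capacities[(u, v)]:.10g}\n")
        fh.write(f"# max_flow\t{fr.value:.10g}\n")
        fh.write("# step\tpush_node\tflow\treceived_node\n")
        for i, (u, f, v) in enumerate(fr.pushed_steps, start=1):
            fh.write(f"# {i}\t{u}\t{f:.10g}\t{v}\n")


def write_affected(score: AffectedScore, fn, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node\tF\tK\tP\n")
        for node, p in sorted(score.per_node.items()):
            k = fn.in_degree(node)
            fh.write(f"{node}\t{round(p * k)}\t{k}\t{p:.10g}\n")
        fh.write(f"# AG\t{score.total:.10g}\n")


def write_eval_report(reports: list[EvalReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("method\tmetric\tdetail\tvalue\n")
        for rep in reports:
            if rep.map_score is not None:
                fh.write(f"{rep.method}\tmAP\t\t{rep.map_score:.6g}\n")
            for level, prec in rep.pr_points:
                fh.write(f"{rep.method}\tprecision\trecall={level:.4g}\t{prec:.6g}\n")
            for row in rep.topk:
                ap = "N/A" if row.average_position is None else f"{row.average_position:.6g}"
                fh.write(
                    f"{rep.method}\ttopk\tfrac={row.fraction:g},k={row.k},"
                    f"count={row.count}\t{ap}\n"
                )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write the full synthetic input bundle to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(ds.matrix, outdir / "expression.tsv")
    write_condition_map(ds.matrix.condition, outdir / "conditions.tsv")
    write_edges(ds.records, outdir / "edges.tsv")
    write_gene_list(ds.candidates, outdir / "candidates.txt")
    write_gene_list(ds.disease, outdir / "disease.txt")
    write_gene_list(ds.planted_targets, outdir / "planted_targets.txt")
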