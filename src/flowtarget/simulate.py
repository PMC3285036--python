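"""Synthetic inputs: the worked-example toy network, random flow instances
for solver cross-checks, and module-structured expression datasets with
planted drug targets.

All generators are pure functions of their seed and parameters and are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import CANCER, NORMAL, ExpressionMatrix
from .flow import FlowNetwork, build_flow_network
from .network import InteractionRecord, WeightedNetwork

# ---------------------------------------------------------------------------
# worked-example toy network
# ---------------------------------------------------------------------------


@dataclass
class Figure2Fixture:
    """Seven-gene toy network reconstructing the published worked example.

    Only the capacities on the flow-carrying arcs for candidate G1 are
    printed in the source material (G1→G6: 1.83, G1→G3: 0.69, G3→G7: 0.90);
    the padding arcs are directed *into* the padded nodes so that G1, G3, G6
    and G7 each have augmented in-degree 2 without creating any alternative
    source-to-sink path for candidate G1. The printed values for candidate
    G2 are not recoverable and are not asserted.
    """

    network: WeightedNetwork
    candidates: set[str] = field(default_factory=lambda: {"G1", "G2"})
    disease: set[str] = field(default_factory=lambda: {"G6", "G7"})
    expected: dict[str, float] = field(default_factory=dict)


#: (u, v, capacity) — first three arcs carry the candidate-G1 flow, the rest
#: pad in-degrees without adding S→T paths for G1
_FIG2_ARCS = [
    ("G1", "G6", 1.83),
    ("G1", "G3", 0.69),
    ("G3", "G7", 0.90),
    ("G4", "G1", 0.50),
    ("G2", "G3", 1.00),
    ("G2", "G6", 1.20),
    ("G5", "G7", 0.80),
]


def figure2_fixture() -> Figure2Fixture:
    net = WeightedNetwork()
    for u, v, cap in _FIG2_ARCS:
        net.add_arc(u, v, cap, "regulatory")
    expected = {
        "flow_G1": 2.52,
        "ag_G1": 2.0,
        "p_affected": 0.5,
        "height_G1": 2,
        "flow_arc_G3_G7": 0.69,
        "flow_arc_G1_G6": 1.83,
    }
    return Figure2Fixture(network=net, expected=expected)


# ---------------------------------------------------------------------------
# random flow instances for oracle testing
# ---------------------------------------------------------------------------


def random_flow_instance(n_nodes: int, n_arcs: int, seed: int) -> FlowNetwork:
    """Random directed capacity network with dummy source/sink attached.

    A permutation chain through all nodes keeps the instance connected-ish;
    extra arcs are sampled uniformly without replacement, capacities are
    U(0, 2). One random candidate and 1–3 random disease genes are chosen.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if n_arcs < n_nodes - 1 or n_arcs > n_nodes * (n_nodes - 1):
        raise ValueError("n_arcs out of range")
    rng = np.random.default_rng(seed)
    names = [f"N{i:03d}" for i in range(n_nodes)]
    perm = list(rng.permutation(names))
    arcs = {(perm[i], perm[i + 1]) for i in range(n_nodes - 1)}
    while len(arcs) < n_arcs:
        u, v = rng.choice(names, size=2, replace=False)
        arcs.add((str(u), str(v)))
    net = WeightedNetwork()
    for u, v in sorted(arcs):
        net.add_arc(u, v, float(rng.uniform(0.0, 2.0)), "regulatory")
    candidate = perm[0]
    n_disease = int(rng.integers(1, 4))
    others = [g for g in names if g != candidate]
    disease = set(rng.choice(others, size=min(n_disease, len(others)), replace=False))
    disease = {str(d) for d in disease}
    return build_flow_network(net, candidate, disease)


# ---------------------------------------------------------------------------
# planted-structure expression + interaction datasets
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """A reduced-scale stand-in for the tumor/normal microarray + interactome
    input bundle, with known ground truth.

    Genes fall into co-expressed modules driven by shared latent factors in
    the cancer samples; the first module is differentially expressed and
    hosts the disease genes and the planted targets, which are wired to the
    disease genes through high-capacity within-module edges. Decoy
    candidates are background hubs whose edges carry near-zero correlation
    and near-zero differential expression, so they attract degree-based
    rankers but little flow.
    """

    matrix: ExpressionMatrix
    ppi: list[InteractionRecord]
    regulatory: list[InteractionRecord]
    candidates: set[str]
    disease: set[str]
    planted_targets: set[str]
    seed: int

    @property
    def records(self) -> list[InteractionRecord]:
        return self.ppi + self.regulatory


def simulate_dataset(
    n_genes: int = 200,
    n_cancer: int = 20,
    n_normal: int = 15,
    n_modules: int = 4,
    missing_rate: float = 0.05,
    seed: int = 0,
    n_targets: int = 3,
    n_decoys: int = 7,
    n_disease: int = 5,
) -> SyntheticDataset:
    """Generate the expression matrix, interaction lists and gene sets.

    Module genes: value = condition mean + loading × per-sample latent
    factor (cancer only) + N(0, 0.3) noise; the disease module has a +2.0
    cancer shift, the other modules +1.0, background genes no shift.
    Missing entries are sprinkled uniformly at ``missing_rate``.
    """
    if min(n_genes, n_cancer, n_normal, n_modules) < 1:
        raise ValueError("size parameters must be positive")
    if not 0.0 <= missing_rate < 0.5:
        raise ValueError("missing_rate must lie in [0, 0.5)")
    module_size = 30
    if n_modules * module_size + n_decoys > n_genes:
        raise ValueError("n_genes too small for the requested module structure")
    rng = np.random.default_rng(seed)

    genes = [f"G{i:04d}" for i in range(n_genes)]
    samples = [f"C{i:02d}" for i in range(n_cancer)] + [
        f"N{i:02d}" for i in range(n_normal)
    ]
    condition = {s: (CANCER if s.startswith("C") else NORMAL) for s in samples}

    modules = [
        genes[m * module_size : (m + 1) * module_size] for m in range(n_modules)
    ]
    background = genes[n_modules * module_size :]

    noise_sd = 0.3
    values = rng.normal(0.0, 0.5, size=(n_genes, len(samples)))
    gene_index = {g: i for i, g in enumerate(genes)}
    for m, member in enumerate(modules):
        shift = 2.0 if m == 0 else 1.0
        z = rng.normal(0.0, 1.0, size=n_cancer)
        for g in member:
            load = rng.uniform(0.8, 1.2)
            row = gene_index[g]
            values[row, :n_cancer] = shift + load * z + rng.normal(
                0.0, noise_sd, size=n_cancer
            )
            values[row, n_cancer:] = rng.normal(0.0, noise_sd, size=n_normal)

    disease = set(modules[0][:n_disease])
    planted = set(modules[0][n_disease : n_disease + n_targets])
    decoys = set(background[:n_decoys])
    candidates = planted | decoys

    ppi: list[InteractionRecord] = []
    regulatory: list[InteractionRecord] = []
    disease_sorted = sorted(disease)
    # planted targets: high-capacity within-module edges to disease genes
    for t_i, t in enumerate(sorted(planted)):
        linked = [disease_sorted[(t_i + j) % len(disease_sorted)] for j in range(3)]
        for d in linked[:-1]:
            ppi.append(InteractionRecord(t, d, directed=False, source="planted"))
        regulatory.append(
            InteractionRecord(t, linked[-1], directed=True, source="planted")
        )
    # within-module chains for co-expression realism
    for member in modules:
        for a, b in zip(member, member[1:]):
            ppi.append(InteractionRecord(a, b, directed=False, source="module"))
    # decoys: background hubs with a couple of weak disease links
    hub_pool = [g for g in background if g not in decoys]
    for d_i, dec in enumerate(sorted(decoys)):
        spokes = rng.choice(hub_pool, size=12, replace=False)
        for s in spokes:
            ppi.append(InteractionRecord(dec, str(s), directed=False, source="decoy"))
        for j in range(2):
            ppi.append(
                InteractionRecord(
                    dec,
                    disease_sorted[(d_i + j) % len(disease_sorted)],
                    directed=False,
                    source="decoy",
                )
            )
    # sparse random background edges
    n_extra = n_genes // 2
    for _ in range(n_extra):
        a, b = rng.choice(genes, size=2, replace=False)
        if a != b:
            ppi.append(InteractionRecord(str(a), str(b), directed=False, source="rand"))

    if missing_rate > 0.0:
        mask = rng.random(size=values.shape) < missing_rate
        # keep at least one observed entry per gene
        full = mask.all(axis=1)
        mask[full, 0] = False
        values = values.copy()
        values[mask] = np.nan

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), condition
    )
    return SyntheticDataset(
        matrix=matrix,
        ppi=ppi,
        regulatory=regulatory,
        candidates=candidates,
        disease=disease,
        planted_targets=planted,
        seed=seed,
    )
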