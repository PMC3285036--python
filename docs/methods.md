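# Methods

## Model

The method treats drug-target prioritization as a single-source,
single-sink maximum-flow problem on a capacity-weighted, partially directed
gene network. The modeling assumptions are:

1. **Partial directedness.** A PPI transmits influence both ways and is
   expanded into two independent antiparallel arcs, each with the full edge
   capacity (not a shared budget); a TF→gene regulation transmits one way.
   This is the standard reduction of mixed graphs to directed flow networks
   and reproduces the worked example.
2. **Co-expression capacity.** Arc (i, j) carries
   `w_ij = |R_ij|·(|E_ci−E_ni|+|E_cj−E_nj|)`, with the Pearson correlation
   computed over **cancer samples only** (the target is drugged in the
   disease state) and ΔE the cancer-minus-normal mean log2 ratio. Both
   regulatory and PPI arcs use this weighting; no separate protein–DNA
   weighting is defined. Zero-capacity arcs stay in the graph but are never
   admissible for flow.
3. **Dummy augmentation.** Per candidate: one arc S→candidate and one arc
   disease-gene→T for every disease gene *not* in the candidate set (a
   disease gene that is also a candidate would otherwise score unbounded
   flow trivially). "Infinite" capacity is realized as
   `big_M = (sum of all finite capacities) + 1`; any larger value is
   equivalent and this keeps arithmetic finite.

## Algorithms and numerical conventions

* **Push-relabel** with heights initialized to BFS hop distance to T
  (unreachable nodes get the sentinel |V|; the source is pinned at |V|).
  Active nodes are processed highest-label first with a FIFO tie-break on
  the deterministic node order; a global BFS relabel runs every |V| relabel
  operations. Excess below 1e-12 counts as drained.
* **Per-arc flows** are recovered from the final residual capacities
  (`f(u,v) = c(u,v) − r(u,v)`, positive side of each antiparallel pair), so
  capacity bounds hold exactly even when both orientations of a pair are
  original arcs.
* **Canonical solution.** A maximum flow's *value* is unique; its per-arc
  decomposition is not. All iteration follows lexicographic node order and
  uses no randomness, so repeated runs are bit-identical. The affected-genes
  score (which counts flow-carrying arcs) is defined on this canonical
  solution; a different solver could legitimately report a different AG for
  the same flow value. The reported "step log" renders the canonical
  solution as (push node, flow, received node) rows ordered by BFS distance
  from S — on the worked example this reproduces the published step table.
* **Solver verification.** An independent Edmonds–Karp (shortest augmenting
  path) implementation serves as a test oracle; on small instances the flow
  value is additionally checked against exhaustive S–T cut enumeration and
  against networkx's max-flow routine.
* **Affected-genes score.** `P_i = F_i/K_i` uses the in-degree of the
  *augmented* graph: the dummy S→candidate arc counts toward both F and K of
  the candidate, while S and T themselves are excluded from the sum. This is
  the only reading consistent with the worked example (candidate P = 0.5
  with flow arriving via S, total AG = 2). Disease genes receiving flow are
  included.

## Preprocessing

* Genes with **more than** 20% missing entries are removed (a gene at
  exactly 20% is kept); the threshold is configurable.
* Missing values are imputed by k-nearest-neighbor genes (default k = 10):
  Euclidean distance over mutually observed samples, inverse-distance
  weighted mean of the k nearest genes observed at that sample; a
  zero-distance neighbor supplies its value directly, and fewer than k
  usable neighbors fall back to all available ones with a warning.
  Correlations are computed **after** imputation.
* Zero-variance genes get correlation 0 (undefined Pearson; the edge then
  carries no flow). The t-test baseline uses the Welch statistic with a
  1e-12 floor on the standard error, ranked by |t|.

## Ranking threshold

The top set is cut at `mean + z_(1−tail) · sd` (sample sd, default tail
0.05, z_0.95 ≈ 1.6449) of the empirical per-candidate flow distribution —
the upper-tail bound of a normal fitted by moments, per the central-limit
appeal. The empirical distribution is typically right-skewed, so the
selected fraction can exceed the nominal tail.

## Baselines

Degree counts incident links (a PPI pair once, a directed arc once, at both
endpoints). Entropy is the Shannon entropy of a node's neighbor-degree
distribution — the underlying reference gives no formula, so this
degree-distribution reading is a documented interpretation. Betweenness and
closeness use distances d = 1/w (zero-capacity arcs unusable); closeness is
outgoing, `(n_reachable − 1)/Σd`, computed within the reachable set. The
restart walk uses capacity-proportional transitions with restart probability
α = 0.3 at the candidate and dangling mass returned to the candidate
(networkx pagerank with a one-hot personalization); the score is the
stationary mass on the disease genes. mAP is interpolated average precision
over attained recall levels; top-k windows use k = round(fraction·n), at
least 1, and report N/A when empty. Direction randomization collapses every
PPI pair to one fair-coin direction (seeded), leaving regulatory arcs and
capacities untouched; the rank-vs-flow trend is fit as y = a·ln(x) + b by
least squares.

## Synthetic data

`simulate_dataset` emulates the input shape of a two-condition microarray
study plus interactome at reduced scale. Defaults: 200 genes × (20 cancer +
15 normal) samples, 4 co-expression modules of 30 genes driven by shared
per-sample latent factors (loadings U(0.8, 1.2), residual sd 0.3), a +2.0
log2 cancer shift in the disease module and +1.0 in the others, 5% missing
entries, 5 disease genes and 3 planted targets inside the disease module,
and 7 decoy candidates built as background hubs (12 spokes plus 2 weak
disease links). Planted targets connect to disease genes through
within-module edges, which get high capacity (correlation ≈ 0.9, both ΔE ≈
2); decoy edges join non-differential, near-uncorrelated genes and get
capacity well below 1, so planted targets out-rank decoys by construction
while the decoys' hub degree baits the degree baseline — mimicking the known
hub bias of degree centrality. The generator does not emulate two-channel
array noise physics, batch effects, heavy-tailed expression or the true
interactome's degree distribution; recovery results on it demonstrate
correctness of the machinery, not real-data performance. Problem sizes for
the recovery experiment (50 replicates at these defaults) were chosen so the
full study runs in well under a minute.

## Known limitations

* AG depends on the canonical flow decomposition (documented above); values
  on real data may differ between solvers even at identical flow values.
* Published real-data results (top-target tables, real mAP, the fitted trend
  coefficients) require the original tumor cohort and drug/disease-gene
  databases, which are deliberately outside this package's input contract;
  the pipeline reproduces the report *formats* on synthetic bundles instead.
* The worked-example network is only partially printed in the source
  material; the padding arcs here are directed into the flow-carrying nodes
  so that the printed flow, heights and affected ratios are forced, but the
  second candidate's printed values are not recoverable and are not
  asserted.
* The solver is pure Python and comfortable up to tens of thousands of
  arcs per candidate solve; very large interactomes would warrant a
  compiled max-flow kernel.
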