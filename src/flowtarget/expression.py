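"""Expression-matrix preprocessing for the weighted interactome.

Cleans a genes × samples log2-ratio matrix (missingness filter, KNN
imputation over gene neighbors) and exposes the per-gene condition means,
cancer-sample Pearson correlations and Welch t statistics that feed the
edge-capacity weighting and the differential-expression baseline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CANCER = "cancer"
NORMAL = "normal"


@dataclass
class ExpressionMatrix:
    """A genes × samples grid of log2 expression ratios.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns; missing
        entries are NaN.
    condition
        Map sample id -> ``"cancer"`` or ``"normal"``; must cover every
        sample column.
    """

    values: pd.DataFrame
    condition: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes)[:5]}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing_cond = [s for s in self.values.columns if s not in self.condition]
        if missing_cond:
            raise ValueError(f"samples without condition label: {missing_cond[:5]}")
        bad = {c for c in self.condition.values()} - {CANCER, NORMAL}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.condition[s] == condition]

    @property
    def cancer_values(self) -> pd.DataFrame:
        return self.values[self.samples_of(CANCER)]

    @property
    def normal_values(self) -> pd.DataFrame:
        return self.values[self.samples_of(NORMAL)]

    def has_missing(self) -> bool:
        return bool(self.values.isna().any().any())


def filter_genes_by_missingness(
    matrix: ExpressionMatrix, max_missing_fraction: float = 0.2
) -> ExpressionMatrix:
    """Drop genes whose missing fraction exceeds ``max_missing_fraction``.

    A gene at exactly the threshold is retained (strictly-greater removal).
    Sample set, sample order and the surviving gene order are preserved.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must lie in [0, 1]")
    if matrix.values.empty:
        raise ValueError("empty expression matrix")
    frac = matrix.values.isna().mean(axis=1)
    keep = frac <= max_missing_fraction
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("missingness filter removed %d of %d genes", n_drop, len(frac))
    if not keep.any():
        logger.warning("missingness filter removed every gene")
    return ExpressionMatrix(matrix.values.loc[keep].copy(), dict(matrix.condition))


def knn_impute(matrix: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Fill missing entries from the k nearest gene profiles.

    Distance between two genes is the Euclidean distance over samples where
    both are observed. Each missing entry becomes the inverse-distance
    weighted mean of the k nearest genes observed at that sample; a distance
    of zero gets the neighbor's value directly. If fewer than k usable
    neighbors exist the available ones are used with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = matrix.values.to_numpy(dtype=float, copy=True)
    mask = np.isnan(vals)
    if not mask.any():
        return ExpressionMatrix(matrix.values.copy(), dict(matrix.condition))
    all_missing = mask.all(axis=1)
    if all_missing.any():
        bad = matrix.values.index[all_missing]
        raise ValueError(f"gene missing in every sample: {list(bad)[:5]}")

    n_genes = vals.shape[0]
    out = vals.copy()
    for g in np.flatnonzero(mask.any(axis=1)):
        # distances to every other gene over mutually observed samples
        both = ~mask[g] & ~mask
        diff = vals[g] - vals
        with np.errstate(invalid="ignore"):
            sq = np.where(both, diff * diff, 0.0)
        n_common = both.sum(axis=1)
        dist = np.sqrt(sq.sum(axis=1))
        for s in np.flatnonzero(mask[g]):
            usable = (~mask[:, s]) & (n_common > 0)
            usable[g] = False
            cand = np.flatnonzero(usable)
            if cand.size == 0:
                raise ValueError(
                    f"no neighbor observed at sample column {s} for gene row {g}"
                )
            if cand.size < k:
                logger.warning(
                    "only %d neighbors available (k=%d) for gene row %d", cand.size, k, g
                )
            order = cand[np.lexsort((cand, dist[cand]))]
            nearest = order[:k]
            d = dist[nearest]
            if np.any(d == 0.0):
                out[g, s] = vals[nearest[d == 0.0], s].mean()
            else:
                w = 1.0 / d
                out[g, s] = float(np.dot(w, vals[nearest, s]) / w.sum())
    assert n_genes == out.shape[0]
    imputed = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(imputed, dict(matrix.condition))


def condition_mean(matrix: ExpressionMatrix, gene: str, condition: str) -> float:
    """Mean expression of ``gene`` over samples of one condition."""
    if gene not in matrix.values.index:
        raise KeyError(f"unknown gene {gene!r}")
    samples = matrix.samples_of(condition)
    if not samples:
        raise ValueError(f"no samples with condition {condition!r}")
    return float(matrix.values.loc[gene, samples].mean())


def pearson_cancer(matrix: ExpressionMatrix, gene_i: str, gene_j: str) -> float:
    """Pearson correlation of two gene profiles over cancer samples only.

    Returns 0.0 when either profile has zero variance (the correlation is
    undefined and the downstream edge weight should carry no flow).
    """
    for g in (gene_i, gene_j):
        if g not in matrix.values.index:
            raise KeyError(f"unknown gene {g!r}")
    samples = matrix.samples_of(CANCER)
    if len(samples) < 2:
        raise ValueError("need at least 2 cancer samples for correlation")
    x = matrix.values.loc[gene_i, samples].to_numpy(dtype=float)
    y = matrix.values.loc[gene_j, samples].to_numpy(dtype=float)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return max(-1.0, min(1.0, r))


#: floor on the Welch standard error so zero-variance groups stay finite
_SE_FLOOR = 1e-12


def ttest_statistic(matrix: ExpressionMatrix, gene: str) -> float:
    """Welch two-sample t statistic, cancer minus normal, for one gene.

    The standard error is floored at a tiny epsilon so that groups with zero
    within-group variance but different means yield a large finite statistic
    instead of infinity; equal constant groups yield 0.
    """
    if gene not in matrix.values.index:
        raise KeyError(f"unknown gene {gene!r}")
    c = matrix.values.loc[gene, matrix.samples_of(CANCER)].to_numpy(dtype=float)
    n = matrix.values.loc[gene, matrix.samples_of(NORMAL)].to_numpy(dtype=float)
    if len(c) < 2 or len(n) < 2:
        raise ValueError("need >= 2 samples per condition for the t statistic")
    delta = c.mean() - n.mean()
    se = math.sqrt(c.var(ddof=1) / len(c) + n.var(ddof=1) / len(n))
    if delta == 0.0:
        return 0.0
    return float(delta / max(se, _SE_FLOOR))
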