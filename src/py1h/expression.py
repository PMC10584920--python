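"""Expression specificity (TCESS) and Simpson co-expression scores.

Works on a cluster-level expression matrix (genes x cell clusters, summed
per-cell normalized expression). The tissue/cell-type expression
specificity score of a gene is the entropy-based statistic

    TCESS = sum_c f_c * log2( f_c / mean(f) ),   f_c = Exp_c / sum(Exp)

over the C clusters, where Exp carries a +1 pseudocount. Since
``mean(f) = 1/C`` this equals ``log2(C) - H(f)`` with H the Shannon entropy
in bits: 0 for a gene expressed identically everywhere, up to ``log2(C)``
(about 7.54 for 187 clusters) for a gene expressed in a single cluster.

Co-expression of two genes uses the Simpson overlap of their
expressed-cluster sets (a gene is "expressed" in a cluster when its cpm
exceeds 10% of its maximum across clusters):

    Simpson = |A ∩ B| / min(|A|, |B|)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "cluster_expression",
    "tcess",
    "tcess_matrix",
    "expressed_clusters",
    "simpson_coexpression",
    "CoexpressionRecord",
]


def cluster_expression(
    cell_matrix: pd.DataFrame,
    cluster_assignment: pd.Series,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Sum per-cell expression within clusters, adding the pseudocount.

    ``cell_matrix`` is genes x cells (normalized expression);
    ``cluster_assignment`` maps each cell (column) to its cluster. Empty
    clusters get the pseudocount alone.
    """
    missing = set(cell_matrix.columns) - set(cluster_assignment.index)
    if missing:
        raise ValueError(f"{len(missing)} cells lack a cluster assignment")
    sums = cell_matrix.T.groupby(cluster_assignment).sum().T
    return sums + pseudocount


def tcess(row: np.ndarray | pd.Series) -> float:
    """Specificity score (bits) of one gene's cluster expression row.

    The row must be strictly positive (cluster sums with pseudocount).
    """
    x = np.asarray(row, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 clusters")
    if (x <= 0).any():
        raise ValueError("cluster expression must be strictly positive (pseudocount applied?)")
    if np.all(x == x[0]):
        return 0.0  # identical expression everywhere: exactly zero
    f = x / x.sum()
    c = x.size
    return float(np.sum(f * np.log2(f * c)))


def tcess_matrix(matrix: pd.DataFrame) -> pd.Series:
    """TCESS for every gene row of a cluster expression matrix."""
    x = matrix.to_numpy(dtype=float)
    if (x <= 0).any():
        raise ValueError("cluster expression must be strictly positive (pseudocount applied?)")
    f = x / x.sum(axis=1, keepdims=True)
    c = x.shape[1]
    scores = np.sum(f * np.log2(f * c), axis=1)
    scores[np.all(x == x[:, :1], axis=1)] = 0.0
    return pd.Series(scores, index=matrix.index, name="tcess")


def expressed_clusters(cpm_row: pd.Series, fraction: float = 0.10) -> set:
    """Clusters where a gene's cpm strictly exceeds ``fraction`` of its maximum.

    An all-zero row yields the empty set.
    """
    x = cpm_row.astype(float)
    mx = x.max()
    if mx <= 0:
        return set()
    return set(x.index[x > fraction * mx])


@dataclass(frozen=True)
class CoexpressionRecord:
    gene_a: str
    gene_b: str
    n_a: int
    n_b: int
    n_shared: int
    simpson: float
    defined: bool


def simpson_coexpression(set_a: set, set_b: set, gene_a: str = "a", gene_b: str = "b") -> CoexpressionRecord:
    """Simpson overlap of two expressed-cluster sets.

    ``|A ∩ B| / min(|A|, |B|)`` — the denominator is the more
    tissue-specific gene's cluster count. Undefined (flagged) when either
    set is empty.
    """
    n_a, n_b = len(set_a), len(set_b)
    shared = len(set_a & set_b)
    if n_a == 0 or n_b == 0:
        return CoexpressionRecord(gene_a, gene_b, n_a, n_b, shared, float("nan"), False)
    return CoexpressionRecord(gene_a, gene_b, n_a, n_b, shared, shared / min(n_a, n_b), True)
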