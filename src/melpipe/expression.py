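"""Variance-stabilized expression, variable-gene PCA, and signature scores.

The transform is a deliberately simple stand-in for a fitted
variance-stabilizing transform: median-of-ratios size factors (the DESeq
convention) followed by log2(count / size_factor + 1). Downstream steps —
ranking genes by across-sample standard deviation, PCA of samples on the
top-k variable genes, and mean-z-score signature scoring — only require
variance stabilization in spirit, not a particular fitted curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gmean
from sklearn.decomposition import PCA

__all__ = [
    "PcaResult",
    "vst_like_transform",
    "size_factors",
    "select_variable_genes",
    "run_pca",
    "signature_score",
]


@dataclass(frozen=True)
class PcaResult:
    scores: pd.DataFrame  # samples x components
    explained_variance_fraction: np.ndarray
    n_genes_used: int


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample.

    The reference is the genewise geometric mean across samples; genes with
    a zero count in any sample are excluded from the median, as in the
    DESeq estimator.
    """
    if (counts.sum(axis=0) == 0).any():
        bad = counts.columns[counts.sum(axis=0) == 0].tolist()
        raise ValueError(f"samples with all-zero counts: {bad}")
    positive = counts.loc[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError("no gene has nonzero counts in every sample")
    ref = gmean(positive.to_numpy(dtype=float), axis=1)
    ratios = positive.to_numpy(dtype=float) / ref[:, None]
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def vst_like_transform(counts: pd.DataFrame) -> pd.DataFrame:
    """Normalize by size factors and apply log2(x + 1).

    Monotone in counts within each sample; a zero count maps to exactly 0.
    """
    sf = size_factors(counts)
    values = np.log2(counts.to_numpy(dtype=float) / sf.to_numpy()[None, :] + 1.0)
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)


def select_variable_genes(matrix: pd.DataFrame, k: int = 10_000) -> pd.DataFrame:
    """Top-k genes by across-sample standard deviation.

    Ties break deterministically by gene identifier (ascending). If fewer
    than k genes are present, all are kept with a warning. Rows are
    returned in rank order, most variable first.
    """
    if k > len(matrix):
        warnings.warn(
            f"k={k} exceeds {len(matrix)} genes; keeping all", stacklevel=2
        )
        k = len(matrix)
    sd = matrix.std(axis=1, ddof=1)
    order = pd.DataFrame(
        {"sd": sd.to_numpy(), "gene_id": matrix.index.to_numpy()}, index=matrix.index
    ).sort_values(["sd", "gene_id"], ascending=[False, True], kind="mergesort")
    return matrix.loc[order.index[:k]]


def run_pca(matrix: pd.DataFrame, n_components: int = 2) -> PcaResult:
    """PCA of samples on gene-centered expression.

    Genes are centered but not scaled to unit variance — the variable-gene
    step selects for variance, and rescaling would undo it. Uses the full
    SVD solver for determinism.
    """
    n_samples = matrix.shape[1]
    max_comp = min(n_samples, matrix.shape[0])
    if n_components > max_comp:
        warnings.warn(
            f"n_components={n_components} clipped to {max_comp}", stacklevel=2
        )
        n_components = max_comp
    x = matrix.to_numpy(dtype=float).T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    return PcaResult(
        scores=pd.DataFrame(
            scores,
            index=matrix.columns,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        ),
        explained_variance_fraction=pca.explained_variance_ratio_,
        n_genes_used=matrix.shape[0],
    )


def signature_score(
    matrix: pd.DataFrame, gene_set: list[str]
) -> tuple[pd.Series, int]:
    """Per-sample mean of genewise z-scores over a gene set.

    Genes are z-scored across samples (constant genes contribute 0); the
    score for each sample is the mean over genes present in both the set
    and the matrix. Returns ``(scores, n_genes_matched)``; an empty
    intersection is an error.
    """
    present = [g for g in dict.fromkeys(gene_set) if g in matrix.index]
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    sub = matrix.loc[present].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    z = np.divide(sub - mu, sd, out=np.zeros_like(sub), where=sd > 0)
    scores = pd.Series(z.mean(axis=0), index=matrix.columns, name="signature_score")
    return scores, len(present)
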