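"""Sample-level projections: PCA over a gene subset and z-score gene panels."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .containers import ExpressionMatrix
from .normalize import log_z


@dataclass
class PcaResult:
    """Sample scores, explained-variance fractions and gene loadings."""

    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # genes x components
    mean: np.ndarray  # per-gene centering offsets

    @property
    def component_names(self) -> list[str]:
        return list(self.scores.columns)


def pca_samples(
    expr: ExpressionMatrix,
    gene_subset: Sequence[str] | None = None,
    k: int = 2,
) -> PcaResult:
    """PCA with samples as observations over a gene subset.

    Deterministic sign convention: within each component the largest-magnitude
    gene loading is made positive.  ``k`` may not exceed min(n_samples,
    n_genes).
    """
    genes = list(gene_subset) if gene_subset is not None else list(expr.gene_ids)
    if not genes:
        raise ValueError("gene subset must be non-empty")
    gidx = expr.gene_indices(genes)
    x = expr.values[gidx].T  # samples x genes
    if not 1 <= k <= min(x.shape):
        raise ValueError(f"k={k} exceeds min(n_samples, n_genes)={min(x.shape)}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_.T.copy()  # genes x k
    for j in range(k):
        lead = np.argmax(np.abs(loadings[:, j]))
        if loadings[lead, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    names = [f"PC{j + 1}" for j in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=list(expr.column_ids), columns=names),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        loadings=pd.DataFrame(loadings, index=genes, columns=names),
        mean=pca.mean_.copy(),
    )


def gene_panel_heatmap_values(
    expr: ExpressionMatrix,
    gene_list: Sequence[str],
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene z-scores of log2(x+1) for a gene panel, rows in input order.

    Genes absent from the matrix are reported in a warning and skipped.  At
    least two samples are required (z-scores are undefined for one).
    """
    cols = list(columns) if columns is not None else list(expr.column_ids)
    if len(cols) < 2:
        raise ValueError("z-scoring a gene panel requires at least 2 samples")
    present = set(expr.gene_ids)
    kept = [g for g in gene_list if g in present]
    missing = [g for g in gene_list if g not in present]
    if missing:
        warnings.warn(f"panel genes not in matrix (skipped): {missing}")
    if not kept:
        return pd.DataFrame(columns=cols)
    z = log_z(expr, cols)
    return z.to_frame().loc[kept]
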