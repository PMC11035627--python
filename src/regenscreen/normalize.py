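"""Expression normalization: TPM, CPM, log transform and per-gene z-scores.

These are the units every downstream stage works in: TPM (gene-length and
library-size normalized) for the bulk screens, CPM for single-cell data, and
log2(x+1) followed by per-gene z-scoring for heatmaps, PCA and population
profiles.
"""

from __future__ import annotations

import warnings

import numpy as np
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, ExpressionMatrix


def _scale_to_million(rate: np.ndarray, column_ids, what: str) -> np.ndarray:
    colsum = rate.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        warnings.warn(
            f"{what}: all-zero column(s) {[c for c, z in zip(column_ids, zero) if z]}; "
            "returning zeros for them",
            stacklevel=3,
        )
    safe = np.where(zero, 1.0, colsum)
    return rate / safe * 1e6 * (~zero)


def tpm(counts: CountMatrix) -> ExpressionMatrix:
    """Transcripts Per Million.

    Per column: ``rate_g = count_g / length_g``; ``tpm_g = 1e6 rate_g / sum(rate)``.
    Requires gene lengths (nucleotides).  Columns sum to 1e6; all-zero columns
    stay zero with a warning.
    """
    if counts.gene_lengths is None:
        raise ValueError("TPM requires gene_lengths on the count matrix")
    rate = counts.counts / counts.gene_lengths[:, None]
    values = _scale_to_million(rate, counts.column_ids, "tpm")
    return ExpressionMatrix(list(counts.gene_ids), list(counts.column_ids), values, "tpm")


def cpm(counts: CountMatrix) -> ExpressionMatrix:
    """Counts Per Million (TPM with unit gene lengths)."""
    rate = counts.counts.astype(float)
    values = _scale_to_million(rate, counts.column_ids, "cpm")
    return ExpressionMatrix(list(counts.gene_ids), list(counts.column_ids), values, "cpm")


def log2p1(m: ExpressionMatrix) -> np.ndarray:
    """log2(x + 1) of the value matrix (helper; unit bookkeeping left to callers)."""
    return np.log2(m.values + 1.0)


def zscore_rows(x: np.ndarray) -> np.ndarray:
    """Per-row z-score with the population (n-denominator) standard deviation.

    Constant rows map to all zeros.
    """
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)  # ddof=0
    safe = np.where(sd == 0, 1.0, sd)
    return (x - mean) / safe * (sd != 0)


def log_z(m: ExpressionMatrix, columns: list[str] | None = None) -> ExpressionMatrix:
    """log2(x+1) then per-gene z-score across the designated column set.

    ``columns`` restricts (and reorders) the sample set the z-score is taken
    over; by default all columns are used.
    """
    if m.unit not in ("tpm", "cpm"):
        raise ValueError(f"log_z expects tpm or cpm input, got {m.unit!r}")
    if columns is None:
        columns = list(m.column_ids)
        vals = m.values
    else:
        vals = m.values[:, m.column_indices(columns)]
    z = zscore_rows(np.log2(vals + 1.0))
    return ExpressionMatrix(list(m.gene_ids), list(columns), z, "zscore")


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1).

    Input p-values must be finite and in [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
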