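"""Two-group differential expression on counts.

The default engine is an exact conditional negative-binomial test: library
sizes are equalized by median-of-ratios scaling, a common dispersion per
contrast is estimated by pooled within-group method of moments, and each gene
is tested two-sidedly on the conditional distribution of its group-B sum given
the total.  Because both group sums share the same NB success probability
under the null, that conditional distribution depends only on the dispersion,
which makes the test cheap and fully specified.

A Welch t-test on log2(TPM+1) (CPM when no gene lengths are available) is
provided as a faster alternative engine.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .containers import CountMatrix
from .normalize import bh_adjust

#: pseudocount added to normalized group means before the log fold change
PSEUDOCOUNT = 0.5

#: dispersion floor (variance = mu + phi mu^2)
DISPERSION_FLOOR = 1e-4

#: minimum number of all-positive genes for median-of-ratios size factors
_MIN_POSITIVE_GENES = 50


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios library-size factors against the geometric-mean reference.

    Falls back to total-count scaling (normalized to geometric-mean total) when
    fewer than 50 genes have all-positive counts.
    """
    counts = np.asarray(counts)
    positive = np.all(counts > 0, axis=1)
    if positive.sum() >= _MIN_POSITIVE_GENES:
        logs = np.log(counts[positive].astype(float))
        ref = logs.mean(axis=1, keepdims=True)
        return np.exp(np.median(logs - ref, axis=0))
    totals = counts.sum(axis=0).astype(float)
    if np.any(totals == 0):
        warnings.warn("column(s) with zero total count get size factor 1", stacklevel=2)
        totals = np.where(totals == 0, 1.0, totals)
    geo = np.exp(np.mean(np.log(totals)))
    return totals / geo


def pooled_dispersion(
    scaled_a: np.ndarray,
    scaled_b: np.ndarray,
    inv_sf_mean_a: float = 1.0,
    inv_sf_mean_b: float = 1.0,
    floor: float = DISPERSION_FLOOR,
) -> float:
    """Common NB dispersion by method of moments, pooled across genes.

    Uses within-group deviations only, so genuinely differential genes do not
    inflate the estimate.  For scaled counts x = k/s, Var(x) ~= mu/s + phi mu^2,
    hence the per-group correction by the mean inverse size factor.
    """
    num = 0.0
    den = 0.0
    for grp, c in ((scaled_a, inv_sf_mean_a), (scaled_b, inv_sf_mean_b)):
        n = grp.shape[1]
        if n < 2:
            continue
        m = grp.mean(axis=1)
        ss = ((grp - m[:, None]) ** 2).sum(axis=1)
        num += float(np.sum(ss - (n - 1) * m * c))
        den += float(np.sum((n - 1) * m**2))
    if den <= 0:
        return floor
    return max(floor, num / den)


def _exact_conditional_pvalues(
    a_sum: np.ndarray, b_sum: np.ndarray, n_a: int, n_b: int, phi: float
) -> np.ndarray:
    """Two-sided exact p-values for the group-B sum given the total.

    Group sums of n iid NB(mu, phi) replicates are NB(n mu, phi/n); under the
    null both share the success probability 1/(1 + phi mu), which cancels in
    the conditional likelihood, leaving
        P(S_b = s | S_a + S_b = t) propto C(s + r_b - 1, s) C(t - s + r_a - 1, t - s)
    with r_g = n_g / phi.  The p-value sums the conditional probabilities of
    all outcomes no more likely than the observed one.
    """
    r_a = n_a / phi
    r_b = n_b / phi
    t_all = a_sum + b_sum
    max_t = int(t_all.max()) if len(t_all) else 0
    grid = np.arange(max_t + 1, dtype=float)
    lfact = gammaln(grid + 1.0)
    half_b = gammaln(grid + r_b) - lfact  # log C(s + r_b - 1, s) + const
    half_a = gammaln(grid + r_a) - lfact
    p = np.ones(len(t_all))
    for i, (t, b) in enumerate(zip(t_all, b_sum)):
        if t == 0:
            continue
        ll = half_b[: t + 1] + half_a[t::-1]
        pr = np.exp(ll - logsumexp(ll))
        # complement of the strictly-more-likely mass, so that an observation at
        # the mode yields exactly 1; the relative tie tolerance must exceed
        # gammaln round-off (~1e-8 on large totals)
        p[i] = float(np.clip(1.0 - pr[pr > pr[b] * (1.0 + 1e-7)].sum(), 0.0, 1.0))
    return p


def de_test_arrays(
    a: np.ndarray,
    b: np.ndarray,
    gene_ids: Sequence[str] | None = None,
    *,
    method: str = "exact",
    gene_lengths: np.ndarray | None = None,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Differential expression of group B over group A on raw count columns.

    Returns a frame with columns ``gene_id log2fc p fdr mean_a mean_b``, where
    the means are library-size-normalized and
    ``log2fc = log2((mean_b + 0.5) / (mean_a + 0.5))``.  Genes with zero counts
    in every column are excluded from the BH family and reported with
    p = fdr = 1.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.ndim != 2 or b.ndim != 2 or a.shape[0] != b.shape[0]:
        raise ValueError("groups must be 2-D with identical gene sets")
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("de_test requires at least 2 replicates per group")
    if method not in ("exact", "t"):
        raise ValueError(f"unknown de method {method!r}")
    n_genes = a.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    elif len(gene_ids) != n_genes:
        raise ValueError("gene_ids length mismatch")

    combined = np.hstack([a, b])
    sf = size_factors(combined)
    sf_a, sf_b = sf[:n_a], sf[n_a:]
    scaled_a = a / sf_a
    scaled_b = b / sf_b
    mean_a = scaled_a.mean(axis=1)
    mean_b = scaled_b.mean(axis=1)
    log2fc = np.log2((mean_b + PSEUDOCOUNT) / (mean_a + PSEUDOCOUNT))

    nonzero = combined.sum(axis=1) > 0
    p = np.ones(n_genes)
    if method == "exact":
        phi = (
            dispersion
            if dispersion is not None
            else pooled_dispersion(
                scaled_a[nonzero],
                scaled_b[nonzero],
                float(np.mean(1.0 / sf_a)),
                float(np.mean(1.0 / sf_b)),
            )
        )
        a_sum = np.rint(scaled_a.sum(axis=1)).astype(np.int64)
        b_sum = np.rint(scaled_b.sum(axis=1)).astype(np.int64)
        p[nonzero] = _exact_conditional_pvalues(
            a_sum[nonzero], b_sum[nonzero], n_a, n_b, phi
        )
    else:
        rate = (
            combined / gene_lengths[:, None] if gene_lengths is not None else combined * 1.0
        )
        colsum = rate.sum(axis=0)
        expr = rate / np.where(colsum == 0, 1.0, colsum) * 1e6  # TPM (CPM w/o lengths)
        la = np.log2(expr[:, :n_a] + 1.0)
        lb = np.log2(expr[:, n_a:] + 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(lb, la, axis=1, equal_var=False)
        pv = np.asarray(res.pvalue, dtype=float)
        same = np.isnan(pv)
        pv[same] = 1.0  # zero variance in both groups => no evidence
        p[nonzero] = pv[nonzero]

    fdr = np.ones(n_genes)
    if nonzero.any():
        fdr[nonzero] = bh_adjust(p[nonzero])
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "mean_a": mean_a,
            "mean_b": mean_b,
        }
    )


def de_test(
    counts: CountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    *,
    method: str = "exact",
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Differential expression between two named column groups of a CountMatrix."""
    a = counts.select_columns(group_a)
    b = counts.select_columns(group_b)
    return de_test_arrays(
        a,
        b,
        counts.gene_ids,
        method=method,
        gene_lengths=counts.gene_lengths,
        dispersion=dispersion,
    )
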