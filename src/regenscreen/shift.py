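"""Developmental-shift analysis.

Quantifies whether a perturbation (transgene induction in the froglet
blastema) moves the blastema expression profile toward the developmental
limb-bud state.  Reference DEGs come from a two-population single-cell
contrast (limb-bud cells vs blastema cells) under marker criteria
(FDR < 0.01, fold change > 2, expressed in >= 10% of cells); perturbation
DEGs come from a Tg-vs-control bulk contrast (FDR < 0.01).  For the genes
common to both sets, the concordance fraction is the proportion whose
transgene-induced direction of change matches the development-over-blastema
direction — the headline "shift toward development" statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix
from .de import de_test
from .normalize import bh_adjust, cpm, zscore_rows

POPULATIONS = ("reference", "contrast")


def _population_indices(sc: CountMatrix, labels: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    labels = labels.reindex(sc.column_ids)
    if labels.isna().any():
        missing = [c for c, v in zip(sc.column_ids, labels.isna()) if v]
        raise ValueError(f"cells without population label: {missing[:5]}")
    bad = set(labels.unique()) - set(POPULATIONS)
    if bad:
        raise ValueError(f"unknown population labels {sorted(bad)}; expected {POPULATIONS}")
    ref = np.flatnonzero((labels == "reference").to_numpy())
    con = np.flatnonzero((labels == "contrast").to_numpy())
    if len(ref) == 0 or len(con) == 0:
        raise ValueError("both populations (reference and contrast) must be non-empty")
    if min(len(ref), len(con)) < 20:
        warnings.warn("fewer than 20 cells in a population; marker tests will be weak")
    return ref, con


def sc_find_markers(
    sc: CountMatrix,
    labels: pd.Series,
    *,
    fdr_threshold: float = 0.01,
    fc_threshold: float = 2.0,
    pct_threshold: float = 0.10,
    pct_rule: str = "both",
) -> pd.DataFrame:
    """Two-population marker detection on CPM with a Wilcoxon rank-sum test.

    Per gene: two-sided rank-sum p across cells, BH-adjusted over genes with
    any expression; fold change ``(mean CPM_ref + 1) / (mean CPM_con + 1)``;
    percent-expressed = fraction of cells with a non-zero count.  A gene
    passes when fdr < threshold, the natural-scale fold change exceeds the
    threshold in either direction, and percent-expressed meets the cutoff in
    both populations (``pct_rule='either'`` relaxes the last criterion).
    """
    if pct_rule not in ("both", "either"):
        raise ValueError(f"unknown pct_rule {pct_rule!r}")
    ref_idx, con_idx = _population_indices(sc, labels)
    vals = cpm(sc).values
    ref, con = vals[:, ref_idx], vals[:, con_idx]
    pct_ref = (sc.counts[:, ref_idx] > 0).mean(axis=1)
    pct_con = (sc.counts[:, con_idx] > 0).mean(axis=1)
    mean_ref, mean_con = ref.mean(axis=1), con.mean(axis=1)
    fold = (mean_ref + 1.0) / (mean_con + 1.0)
    log2fc = np.log2(fold)

    family = sc.counts.sum(axis=1) > 0
    p = np.ones(sc.n_genes)
    if family.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.mannwhitneyu(
                ref[family], con[family], axis=1, alternative="two-sided", method="asymptotic"
            )
        pv = np.asarray(res.pvalue, dtype=float)
        pv[np.isnan(pv)] = 1.0  # fully tied genes carry no evidence
        p[family] = pv
    fdr = np.ones(sc.n_genes)
    if family.any():
        fdr[family] = bh_adjust(p[family])

    fc_ok = (fold > fc_threshold) | (fold < 1.0 / fc_threshold)
    if pct_rule == "both":
        pct_ok = (pct_ref >= pct_threshold) & (pct_con >= pct_threshold)
    else:
        pct_ok = (pct_ref >= pct_threshold) | (pct_con >= pct_threshold)
    passes = family & (fdr < fdr_threshold) & fc_ok & pct_ok
    return pd.DataFrame(
        {
            "gene_id": sc.gene_ids,
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "pct_expressed_reference": pct_ref,
            "pct_expressed_contrast": pct_con,
            "passes": passes,
        }
    )


def zscore_profiles(
    sc: CountMatrix,
    labels: pd.Series,
    n_per_pop: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean per-population z-scores over a pooled random cell subsample.

    Samples ``n_per_pop`` cells per population without replacement (all cells,
    with a warning, when a population is smaller), z-scores log2(CPM+1) per
    gene across the pooled subsample, and averages within each population.
    The pooled-zero identity ``n_ref * mean_ref + n_con * mean_con = 0`` holds
    per gene; the returned frame carries ``n_ref``/``n_con`` in ``attrs``.
    """
    ref_idx, con_idx = _population_indices(sc, labels)
    rng = np.random.default_rng(seed)
    take = []
    for name, idx in (("reference", ref_idx), ("contrast", con_idx)):
        if len(idx) < n_per_pop:
            warnings.warn(
                f"population {name!r} has {len(idx)} cells < n_per_pop={n_per_pop}; using all"
            )
            take.append(idx)
        else:
            take.append(np.sort(rng.choice(idx, n_per_pop, replace=False)))
    ref_take, con_take = take
    pooled = np.concatenate([ref_take, con_take])
    vals = cpm(sc).values[:, pooled]
    z = zscore_rows(np.log2(vals + 1.0))
    n_ref = len(ref_take)
    out = pd.DataFrame(
        {
            "gene_id": sc.gene_ids,
            "mean_z_reference": z[:, :n_ref].mean(axis=1),
            "mean_z_contrast": z[:, n_ref:].mean(axis=1),
        }
    )
    out.attrs["n_ref"] = n_ref
    out.attrs["n_con"] = len(con_take)
    return out


def bulk_deg_tg(
    counts: CountMatrix,
    tg_columns: Sequence[str],
    control_columns: Sequence[str],
    *,
    fdr_threshold: float = 0.01,
    de_method: str = "exact",
) -> pd.DataFrame:
    """Tg-vs-control differential genes at an FDR threshold, with directions.

    ``log2fc`` is Tg over control; ``direction`` its sign; ``selected`` flags
    genes below the FDR threshold.
    """
    res = de_test(counts, control_columns, tg_columns, method=de_method)
    res = res.rename(columns={"mean_a": "mean_control", "mean_b": "mean_tg"})
    res["direction"] = np.sign(res["log2fc"]).astype(int)
    res["selected"] = res["fdr"] < fdr_threshold
    return res


@dataclass
class ShiftReport:
    """Common DEG set with per-gene directions and the concordance fraction."""

    deg_bl_dev: list[str]
    deg_tg: list[str]
    common: pd.DataFrame  # gene_id, reference_direction, perturbation_direction, concordant
    concordance_fraction: float | None

    @property
    def n_common(self) -> int:
        return len(self.common)

    def to_dict(self) -> dict:
        return {
            "n_deg_bl_dev": len(self.deg_bl_dev),
            "n_deg_tg": len(self.deg_tg),
            "n_common": self.n_common,
            "n_concordant": int(self.common["concordant"].sum()) if self.n_common else 0,
            "concordance_fraction": self.concordance_fraction,
        }


def shift_consistency(markers: pd.DataFrame, tg: pd.DataFrame) -> ShiftReport:
    """Concordance of perturbation directions with the developmental reference.

    A common gene (passing marker criteria AND selected in the bulk contrast)
    is concordant when the sign of its reference-over-contrast single-cell
    fold change equals the sign of its Tg-over-control fold change, i.e. the
    transgene moves it in the direction of the developmental state.
    """
    deg_bl_dev = list(markers.loc[markers["passes"], "gene_id"])
    deg_tg = list(tg.loc[tg["selected"], "gene_id"])
    tg_dir = tg.set_index("gene_id")["direction"]
    common_ids = [g for g in deg_bl_dev if g in set(deg_tg)]
    ref_dir = (
        np.sign(markers.set_index("gene_id").loc[common_ids, "log2fc"]).astype(int)
        if common_ids
        else pd.Series(dtype=int)
    )
    common = pd.DataFrame(
        {
            "gene_id": common_ids,
            "reference_direction": ref_dir.to_numpy() if common_ids else [],
            "perturbation_direction": tg_dir.loc[common_ids].to_numpy() if common_ids else [],
        }
    )
    if common.empty:
        warnings.warn("no genes common to both DEG sets; concordance fraction undefined")
        common["concordant"] = pd.Series(dtype=bool)
        return ShiftReport(deg_bl_dev, deg_tg, common, None)
    common["concordant"] = (
        common["reference_direction"] == common["perturbation_direction"]
    )
    frac = float(common["concordant"].mean())
    return ShiftReport(deg_bl_dev, deg_tg, common, frac)
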