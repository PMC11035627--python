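"""The three-step regeneration-specificity screen.

Step 1 keeps genes differentially expressed within at least one of the four
corresponding regeneration/development pairs.  Step 2 keeps, among those, the
genes significantly higher in the distal regenerating region (blastema) than
the proximal stump at one of the two regeneration stages.  Step 3 assigns each
surviving gene a 0-8 point regeneration-specificity score: one point for every
(regeneration-distal, development-distal) condition pair in which the gene's
replicate-mean TPM is strictly higher during regeneration (2 x 4 comparisons
under the default design).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    Condition,
    CountMatrix,
    ExpressionMatrix,
    StudyDesign,
    columns_for_condition,
    default_design,
    validate_sample_sheet,
)
from .de import de_test
from .normalize import tpm


def _condition_columns(
    sheet: pd.DataFrame, conds: Sequence[Condition], min_replicates: int = 2
) -> dict[Condition, list[str]]:
    out = {}
    missing = []
    for cond in conds:
        cols = columns_for_condition(sheet, cond)
        if len(cols) < min_replicates:
            missing.append(f"{cond.long_name} ({len(cols)} replicate(s))")
        out[cond] = cols
    if missing:
        raise ValueError("missing/underreplicated condition(s): " + "; ".join(missing))
    return out


def screen1_corresponding_pairs(
    counts: CountMatrix,
    sheet: pd.DataFrame,
    design: StudyDesign | None = None,
    alpha: float = 0.05,
    rule: str = "union",
    de_method: str = "exact",
) -> list[str]:
    """Genes differentially expressed (p < alpha) within the corresponding pairs.

    ``rule='union'`` (default) keeps genes DE in at least one of the four
    pairs; ``rule='all'`` requires all four.  Gene order follows the matrix.
    """
    if design is None:
        design = default_design()
    if rule not in ("union", "all"):
        raise ValueError(f"unknown screen-1 rule {rule!r}")
    sheet = validate_sample_sheet(sheet)
    conds = [c for pair in design.corresponding_pairs for c in pair]
    cols = _condition_columns(sheet, conds)
    hits = None
    for reg, dev in design.corresponding_pairs:
        res = de_test(counts, cols[dev], cols[reg], method=de_method)
        sig = (res["p"] < alpha).to_numpy()
        if hits is None:
            hits = sig
        else:
            hits = (hits | sig) if rule == "union" else (hits & sig)
    return [g for g, h in zip(counts.gene_ids, hits) if h]


def screen2_distal_over_proximal(
    counts: CountMatrix,
    sheet: pd.DataFrame,
    gene_set: Sequence[str],
    design: StudyDesign | None = None,
    alpha: float = 0.05,
    rule: str = "any",
    de_method: str = "exact",
) -> list[str]:
    """Genes from ``gene_set`` higher distally than proximally during regeneration.

    A gene passes a stage contrast (regD_t vs regP_t) when p < alpha AND its
    normalized distal mean exceeds the proximal mean; ``rule='any'`` requires
    one of the two stages, ``rule='both'`` requires both.
    """
    if design is None:
        design = default_design()
    if rule not in ("any", "both"):
        raise ValueError(f"unknown screen-2 rule {rule!r}")
    sheet = validate_sample_sheet(sheet)
    unknown = set(gene_set) - set(counts.gene_ids)
    if unknown:
        raise ValueError(f"gene_set contains untested genes: {sorted(unknown)[:5]}")
    contrasts = []
    for reg_d in design.reg_distal_conditions:
        reg_p = Condition("regeneration", "proximal", reg_d.timepoint)
        contrasts.append((reg_d, reg_p))
    cols = _condition_columns(sheet, [c for pair in contrasts for c in pair])
    hits = None
    for reg_d, reg_p in contrasts:
        res = de_test(counts, cols[reg_p], cols[reg_d], method=de_method)
        sig = ((res["p"] < alpha) & (res["mean_b"] > res["mean_a"])).to_numpy()
        hits = sig if hits is None else ((hits | sig) if rule == "any" else (hits & sig))
    in_set = set(gene_set)
    return [g for g, h in zip(counts.gene_ids, hits) if h and g in in_set]


def specificity_score(
    expr: ExpressionMatrix,
    sheet: pd.DataFrame,
    gene_set: Sequence[str],
    design: StudyDesign | None = None,
) -> pd.DataFrame:
    """Score each gene by how many regeneration-vs-development distal comparisons it wins.

    For every regeneration-distal condition r and development-distal condition
    d, a gene earns one point when its replicate-mean TPM in r strictly
    exceeds that in d (max 2 x 4 = 8 under the default design).  Ranking is by
    score descending; ties break by the larger worst-case margin
    ``min_r (mean_r - max_d mean_d)``, then lexicographic gene id.
    Returns a frame (gene_id, score, margin, rank) sorted by rank.
    """
    if design is None:
        design = default_design()
    sheet = validate_sample_sheet(sheet)
    if expr.unit != "tpm":
        raise ValueError(f"specificity_score expects TPM input, got {expr.unit!r}")
    gene_set = list(gene_set)
    if not gene_set:
        return pd.DataFrame(columns=["gene_id", "score", "margin", "rank"])
    conds = list(design.reg_distal_conditions) + list(design.dev_distal_conditions)
    cols = _condition_columns(sheet, conds, min_replicates=1)
    gidx = expr.gene_indices(gene_set)
    cond_means = {
        c: expr.values[np.ix_(gidx, expr.column_indices(cols[c]))].mean(axis=1)
        for c in conds
    }
    reg = np.column_stack([cond_means[c] for c in design.reg_distal_conditions])
    dev = np.column_stack([cond_means[c] for c in design.dev_distal_conditions])
    score = (reg[:, :, None] > dev[:, None, :]).sum(axis=(1, 2))
    margin = (reg - dev.max(axis=1, keepdims=True)).min(axis=1)
    out = pd.DataFrame({"gene_id": gene_set, "score": score, "margin": margin})
    out = out.sort_values(
        ["score", "margin", "gene_id"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def _score_significant(
    counts: CountMatrix,
    sheet: pd.DataFrame,
    gene_set: Sequence[str],
    design: StudyDesign,
    alpha: float,
    de_method: str,
) -> pd.DataFrame:
    """Optional strict scoring: a point requires significantly higher expression."""
    expr = tpm(counts)
    base = specificity_score(expr, sheet, gene_set, design)
    conds_r = list(design.reg_distal_conditions)
    conds_d = list(design.dev_distal_conditions)
    cols = _condition_columns(sheet, conds_r + conds_d)
    gpos = {g: i for i, g in enumerate(counts.gene_ids)}
    idx = [gpos[g] for g in base["gene_id"]]
    score = np.zeros(len(base), dtype=int)
    for r in conds_r:
        for d in conds_d:
            res = de_test(counts, cols[d], cols[r], method=de_method)
            point = ((res["p"] < alpha) & (res["mean_b"] > res["mean_a"])).to_numpy()
            score += point[idx]
    base["score"] = score
    base = base.sort_values(
        ["score", "margin", "gene_id"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    base["rank"] = np.arange(1, len(base) + 1)
    return base


@dataclass
class ScreenResult:
    """Output of the full three-step screen."""

    screen1_genes: list[str]
    screen2_genes: list[str]
    table: pd.DataFrame  # all genes: passed_screen1, passed_screen2, score, margin, rank
    scored: pd.DataFrame  # screen-2 survivors sorted by rank
    top_genes: list[str]
    params: dict

    @property
    def counts_per_step(self) -> dict[str, int]:
        return {
            "n_genes": int(len(self.table)),
            "screen1": len(self.screen1_genes),
            "screen2": len(self.screen2_genes),
            "top": len(self.top_genes),
        }

    def top_by_score(self, k: int) -> list[str]:
        """The k best-ranked genes (deterministic tie-breaking)."""
        return list(self.scored["gene_id"].head(k))

    def max_score_group(self) -> list[str]:
        """All genes achieving the maximal observed score."""
        if self.scored.empty:
            return []
        best = self.scored["score"].max()
        return list(self.scored.loc[self.scored["score"] == best, "gene_id"])


def run_screen_pipeline(
    counts: CountMatrix,
    sheet: pd.DataFrame,
    design: StudyDesign | None = None,
    *,
    alpha: float = 0.05,
    de_method: str = "exact",
    screen1_rule: str = "union",
    screen2_rule: str = "any",
    score_mode: str = "mean",
    top: int = 10,
) -> ScreenResult:
    """Run the three screens end to end and assemble the specificity table.

    The nested structure scored genes <= screen2 <= screen1 <= all genes holds
    by construction.  ``score_mode='significant'`` replaces the raw
    mean-inequality point rule by one requiring p < alpha per comparison.
    """
    if design is None:
        design = default_design()
    if score_mode not in ("mean", "significant"):
        raise ValueError(f"unknown score_mode {score_mode!r}")
    sheet = validate_sample_sheet(sheet)
    s1 = screen1_corresponding_pairs(
        counts, sheet, design, alpha=alpha, rule=screen1_rule, de_method=de_method
    )
    s2 = screen2_distal_over_proximal(
        counts, sheet, s1, design, alpha=alpha, rule=screen2_rule, de_method=de_method
    )
    if not s2:
        warnings.warn("no genes survive the screens; specificity table is empty")
        scored = pd.DataFrame(columns=["gene_id", "score", "margin", "rank"])
    elif score_mode == "mean":
        scored = specificity_score(tpm(counts), sheet, s2, design)
    else:
        scored = _score_significant(counts, sheet, s2, design, alpha, de_method)
    table = pd.DataFrame({"gene_id": counts.gene_ids})
    table["passed_screen1"] = table["gene_id"].isin(set(s1))
    table["passed_screen2"] = table["gene_id"].isin(set(s2))
    table = table.merge(scored, on="gene_id", how="left")
    params = {
        "alpha": alpha,
        "de_method": de_method,
        "screen1_rule": screen1_rule,
        "screen2_rule": screen2_rule,
        "score_mode": score_mode,
        "top": top,
    }
    result = ScreenResult(s1, s2, table, scored, [], params)
    result.top_genes = result.top_by_score(top)
    return result
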