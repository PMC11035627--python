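"""Model-layer API: build a model from data, fit it, inspect a Results object.

Two model classes wrap the functional pipeline the way statistical packages
expose estimators:

* :class:`RegenerationSpecificityScreen` — the three-step screen producing the
  0-8 regeneration-specificity score and ranked candidate list;
* :class:`DevelopmentalShiftModel` — the single-cell/bulk concordance analysis
  quantifying the shift of a perturbed blastema toward the developmental
  limb-bud expression state.

Each ``fit()`` returns a Results object carrying tables, diagnostics and a
``summary()`` text report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import io as rio
from .containers import (
    CountMatrix,
    StudyDesign,
    aggregate_homeologs,
    default_design,
    validate_sample_sheet,
)
from .screen import ScreenResult, run_screen_pipeline
from .shift import ShiftReport, bulk_deg_tg, sc_find_markers, shift_consistency, zscore_profiles


class RegenerationSpecificityScreen:
    """Three-step screen for regeneration-specific genes on a bulk design.

    Parameters
    ----------
    counts
        Gene x sample counts with gene lengths (TPM is used for scoring).
    sample_sheet
        Sample annotations mapping columns to (process, axis, timepoint,
        replicate).
    design
        Study layout; defaults to the 12-condition design with its four
        corresponding pairs.
    """

    def __init__(
        self,
        counts: CountMatrix,
        sample_sheet: pd.DataFrame,
        design: StudyDesign | None = None,
    ):
        self.counts = counts
        self.sample_sheet = validate_sample_sheet(sample_sheet)
        self.design = design if design is not None else default_design()

    @classmethod
    def from_files(cls, counts_tsv, samples_tsv, lengths_tsv=None, design=None):
        counts = rio.read_counts_tsv(counts_tsv, lengths_tsv)
        sheet = rio.read_sample_sheet(samples_tsv)
        return cls(counts, sheet, design)

    def fit(
        self,
        alpha: float = 0.05,
        de_method: str = "exact",
        screen1_rule: str = "union",
        screen2_rule: str = "any",
        score_mode: str = "mean",
        top: int = 10,
    ) -> "ScreenResults":
        res = run_screen_pipeline(
            self.counts,
            self.sample_sheet,
            self.design,
            alpha=alpha,
            de_method=de_method,
            screen1_rule=screen1_rule,
            screen2_rule=screen2_rule,
            score_mode=score_mode,
            top=top,
        )
        return ScreenResults(self, res)


@dataclass
class ScreenResults:
    """Fitted screen: per-step gene lists, the specificity table, rankings."""

    model: RegenerationSpecificityScreen
    result: ScreenResult

    @property
    def screen1_genes(self) -> list[str]:
        return self.result.screen1_genes

    @property
    def screen2_genes(self) -> list[str]:
        return self.result.screen2_genes

    @property
    def table(self) -> pd.DataFrame:
        return self.result.table

    @property
    def scored(self) -> pd.DataFrame:
        return self.result.scored

    @property
    def top_genes(self) -> list[str]:
        return self.result.top_genes

    def top_by_score(self, k: int) -> list[str]:
        return self.result.top_by_score(k)

    def max_score_group(self) -> list[str]:
        return self.result.max_score_group()

    def summary(self) -> str:
        c = self.result.counts_per_step
        lines = [
            "Regeneration-specificity screen",
            "===============================",
            f"genes tested:            {c['n_genes']}",
            f"screen 1 (corresponding pairs, p < {self.result.params['alpha']}): "
            f"{c['screen1']}",
            f"screen 2 (distal > proximal in regeneration):   {c['screen2']}",
            f"max attainable score:    {self.model.design.max_score}",
            "",
            f"top {len(self.top_genes)} genes by score (rank, gene, score, margin):",
        ]
        for _, row in self.scored.head(len(self.top_genes)).iterrows():
            lines.append(
                f"  {int(row['rank']):>4d}  {row['gene_id']:<16s} "
                f"score={int(row['score'])}  margin={row['margin']:.3g}"
            )
        return "\n".join(lines)


class DevelopmentalShiftModel:
    """Concordance of a perturbation with the developmental expression state.

    Parameters
    ----------
    sc_counts, cell_labels
        Two-population single-cell counts; labels map cell ids to
        ``reference`` (developing limb bud) or ``contrast`` (blastema).
    bulk_counts
        Tg-vs-control bulk counts.
    tg_columns, control_columns
        Column ids of the two bulk arms.
    homeolog_map
        Optional gene_id -> group_id mapping applied to both matrices before
        analysis so identifiers are comparable across datasets.
    """

    def __init__(
        self,
        sc_counts: CountMatrix,
        cell_labels: pd.Series,
        bulk_counts: CountMatrix,
        tg_columns: Sequence[str],
        control_columns: Sequence[str],
        homeolog_map: Mapping[str, str] | None = None,
    ):
        if homeolog_map:
            sc_counts = aggregate_homeologs(sc_counts, homeolog_map)
            bulk_counts = aggregate_homeologs(bulk_counts, homeolog_map)
        self.sc_counts = sc_counts
        self.cell_labels = cell_labels
        self.bulk_counts = bulk_counts
        self.tg_columns = list(tg_columns)
        self.control_columns = list(control_columns)

    def fit(
        self,
        fdr_threshold: float = 0.01,
        fc_threshold: float = 2.0,
        pct_threshold: float = 0.10,
        pct_rule: str = "both",
        n_cells: int = 1000,
        seed: int = 0,
        de_method: str = "exact",
    ) -> "ShiftResults":
        markers = sc_find_markers(
            self.sc_counts,
            self.cell_labels,
            fdr_threshold=fdr_threshold,
            fc_threshold=fc_threshold,
            pct_threshold=pct_threshold,
            pct_rule=pct_rule,
        )
        profiles = zscore_profiles(self.sc_counts, self.cell_labels, n_cells, seed)
        tg = bulk_deg_tg(
            self.bulk_counts,
            self.tg_columns,
            self.control_columns,
            fdr_threshold=fdr_threshold,
            de_method=de_method,
        )
        report = shift_consistency(markers, tg)
        params = {
            "fdr_threshold": fdr_threshold,
            "fc_threshold": fc_threshold,
            "pct_threshold": pct_threshold,
            "pct_rule": pct_rule,
            "n_cells": n_cells,
            "seed": seed,
            "de_method": de_method,
        }
        return ShiftResults(self, markers, profiles, tg, report, params)


@dataclass
class ShiftResults:
    """Fitted shift analysis: marker table, z-profiles, bulk DEGs, concordance."""

    model: DevelopmentalShiftModel
    markers: pd.DataFrame
    zprofiles: pd.DataFrame
    deg_tg: pd.DataFrame
    report: ShiftReport
    params: dict

    @property
    def concordance_fraction(self) -> float | None:
        return self.report.concordance_fraction

    def summary(self) -> str:
        d = self.report.to_dict()
        frac = (
            "undefined (no common genes)"
            if d["concordance_fraction"] is None
            else f"{d['concordance_fraction']:.3f}"
        )
        return "\n".join(
            [
                "Developmental-shift analysis",
                "============================",
                f"reference DEGs (single-cell markers): {d['n_deg_bl_dev']}",
                f"perturbation DEGs (Tg vs control):    {d['n_deg_tg']}",
                f"common genes:                         {d['n_common']}",
                f"concordant (shift toward development): {d['n_concordant']}",
                f"concordance fraction:                 {frac}",
            ]
        )
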