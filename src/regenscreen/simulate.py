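"""Synthetic bulk and single-cell datasets with planted ground truth.

Counts follow a negative-binomial model with variance mu + phi * mu^2
(``dispersion`` = phi), so phi -> 0 recovers Poisson sampling.  Each dataset
draws per-gene baseline abundance weights log-uniformly, converts them to
per-column expected counts against a lognormal library size (bulk) or capture
depth (single cell), and plants condition-specific fold changes:

* bulk: *regeneration-specific* genes elevated only in the regeneration-distal
  (blastema) conditions; *distal-shared* genes elevated in all distal columns
  of both processes; *proximal* genes elevated in all proximal columns;
* single cell: marker genes elevated in one of two populations;
* shift pair: a set of common genes differential in both the single-cell
  reference contrast and a transgenic-vs-control bulk contrast, with the two
  directions agreeing at a planted concordance rate.

Planted genes draw their baselines from a moderately expressed range so that
they are genuinely differential at sequencing depth, as their ground-truth
label promises; null genes span the full dynamic range.  All generators are
pure functions of (params, seed): one root seed sequence per dataset with
deterministic per-column children.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    Condition,
    CountMatrix,
    SAMPLE_SHEET_COLUMNS,
    StudyDesign,
    default_design,
)

GROUND_TRUTH_LABELS = (
    "regspecific",
    "distal_shared",
    "proximal",
    "null",
    "marker",
    "concordant",
    "discordant",
)


def sample_negative_binomial(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB draws with variance mean + dispersion * mean^2 (Poisson when ~0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-8:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size=None) -> np.ndarray:
    """Lognormal draws parameterized by arithmetic mean and coefficient of variation."""
    if cv == 0:
        return np.full(size if size is not None else (), mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size) -> np.ndarray:
    if not (0 < lo <= hi):
        raise ValueError(f"invalid log-uniform range ({lo}, {hi})")
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size))


@dataclass
class BulkSimParams:
    """Parameters of the bulk development/regeneration simulator."""

    n_genes: int = 5000
    n_replicates: int = 3
    library_size_mean: float = 1e6
    library_size_cv: float = 0.1
    dispersion: float = 0.1
    n_planted_regspecific: int = 20
    regspecific_fold: float = 8.0
    n_planted_distal_shared: int = 50
    n_planted_proximal: int = 50
    planted_fold: float = 4.0
    gene_length_range: tuple[float, float] = (300.0, 10000.0)
    seed: int = 0
    baseline_weight_range: tuple[float, float] = (1.0, 1e4)
    planted_weight_range: tuple[float, float] = (50.0, 5000.0)

    def validate(self) -> None:
        planted = (
            self.n_planted_regspecific
            + self.n_planted_distal_shared
            + self.n_planted_proximal
        )
        if min(self.n_genes, self.n_replicates) < 1 or planted > self.n_genes:
            raise ValueError("planted gene counts must sum to <= n_genes (all >= 1)")
        if self.regspecific_fold <= 1 or self.planted_fold <= 1:
            raise ValueError("planted folds must be > 1")
        if self.dispersion <= 0 or self.library_size_mean <= 0 or self.library_size_cv < 0:
            raise ValueError("dispersion/library size parameters out of range")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError("gene_length_range must be positive and ordered")


@dataclass
class ScSimParams:
    """Parameters of the two-population single-cell simulator."""

    n_genes: int = 3000
    n_cells_per_population: int = 500
    capture_depth_mean: float = 2000.0
    dispersion: float = 0.1
    n_planted_markers: int = 100
    marker_fold: float = 4.0
    dropout_extra: float = 0.0
    seed: int = 0
    depth_cv: float = 0.3
    baseline_weight_range: tuple[float, float] = (1.0, 1e3)
    marker_weight_range: tuple[float, float] = (50.0, 1e3)

    def validate(self) -> None:
        if self.n_cells_per_population < 2:
            raise ValueError("n_cells_per_population must be >= 2")
        if self.n_planted_markers > self.n_genes:
            raise ValueError("n_planted_markers must be <= n_genes")
        if self.marker_fold <= 1:
            raise ValueError("marker_fold must be > 1")
        if not 0 <= self.dropout_extra <= 1:
            raise ValueError("dropout_extra must lie in [0, 1]")
        if self.dispersion <= 0 or self.capture_depth_mean <= 0:
            raise ValueError("dispersion/depth out of range")


@dataclass
class ShiftSimParams:
    """Parameters of the paired single-cell + transgenic-bulk shift simulator."""

    n_common_genes: int = 2000
    concordance_rate: float = 0.8
    tg_effect_log2: float = 2.0
    seed: int = 0
    n_null_genes: int = 1000
    n_cells_per_population: int = 600
    capture_depth_mean: float = 2000.0
    sc_dispersion: float = 0.1
    marker_fold: float = 4.0
    dropout_extra: float = 0.0
    n_replicates: int = 4
    library_size_mean: float = 1e6
    library_size_cv: float = 0.1
    bulk_dispersion: float = 0.1
    common_weight_range: tuple[float, float] = (50.0, 1e3)
    null_weight_range: tuple[float, float] = (1.0, 1e3)

    def validate(self) -> None:
        if self.n_common_genes < 1 or self.n_null_genes < 0:
            raise ValueError("gene counts out of range")
        if not 0 <= self.concordance_rate <= 1:
            raise ValueError("concordance_rate must lie in [0, 1]")
        if self.tg_effect_log2 <= 0:
            raise ValueError("tg_effect_log2 must be > 0")
        if self.n_cells_per_population < 2 or self.n_replicates < 2:
            raise ValueError("need >= 2 cells per population and >= 2 bulk replicates")


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"gene_{i + 1:0{width}d}" for i in range(n)]


def simulate_bulk(
    design: StudyDesign | None, p: BulkSimParams
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate the 12-condition bulk experiment with planted gene classes.

    Returns ``(counts, sample_sheet, ground_truth)``.  Ground truth has one
    label per gene in {regspecific, distal_shared, proximal, null}.
    """
    p.validate()
    if design is None:
        design = default_design()
    n_columns = len(design.conditions) * p.n_replicates
    root = np.random.SeedSequence(p.seed)
    gene_child, *col_children = root.spawn(1 + n_columns)
    rng = np.random.default_rng(gene_child)

    gene_ids = _gene_ids(p.n_genes)
    labels = np.array(["null"] * p.n_genes, dtype=object)
    perm = rng.permutation(p.n_genes)
    n_rs, n_ds, n_px = (
        p.n_planted_regspecific,
        p.n_planted_distal_shared,
        p.n_planted_proximal,
    )
    labels[perm[:n_rs]] = "regspecific"
    labels[perm[n_rs : n_rs + n_ds]] = "distal_shared"
    labels[perm[n_rs + n_ds : n_rs + n_ds + n_px]] = "proximal"
    planted = labels != "null"

    weights = _log_uniform(rng, *p.baseline_weight_range, p.n_genes)
    weights[planted] = _log_uniform(rng, *p.planted_weight_range, int(planted.sum()))
    lengths = _log_uniform(rng, *p.gene_length_range, p.n_genes)

    reg_distal = set(design.reg_distal_conditions)
    fold_for: dict[Condition, np.ndarray] = {}
    for cond in design.conditions:
        fold = np.ones(p.n_genes)
        if cond in reg_distal:
            fold[labels == "regspecific"] = p.regspecific_fold
        if cond.axis == "distal":
            fold[labels == "distal_shared"] = p.planted_fold
        if cond.axis == "proximal":
            fold[labels == "proximal"] = p.planted_fold
        fold_for[cond] = fold

    counts = np.empty((p.n_genes, n_columns), dtype=np.int64)
    rows = []
    k = 0
    for cond in design.conditions:
        for rep in range(1, p.n_replicates + 1):
            col_rng = np.random.default_rng(col_children[k])
            libsize = float(_lognormal(col_rng, p.library_size_mean, p.library_size_cv))
            w = weights * fold_for[cond]
            mu = libsize * w / w.sum()
            counts[:, k] = sample_negative_binomial(col_rng, mu, p.dispersion)
            rows.append(
                {
                    "column_id": f"{cond.label}_r{rep}",
                    "process": cond.process,
                    "axis": cond.axis,
                    "timepoint": cond.timepoint,
                    "replicate": rep,
                }
            )
            k += 1
    sheet = pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS)
    cm = CountMatrix(gene_ids, list(sheet["column_id"]), counts, gene_lengths=lengths)
    truth = pd.DataFrame({"gene_id": gene_ids, "label": labels})
    return cm, sheet, truth


def _simulate_two_populations(
    gene_ids: Sequence[str],
    weight_ref: np.ndarray,
    weight_con: np.ndarray,
    n_cells: int,
    depth_mean: float,
    depth_cv: float,
    dispersion: float,
    dropout_extra: float,
    root: np.random.SeedSequence,
) -> tuple[CountMatrix, pd.Series]:
    n_genes = len(gene_ids)
    children = root.spawn(2 * n_cells)
    counts = np.empty((n_genes, 2 * n_cells), dtype=np.int64)
    cell_ids, pops = [], []
    k = 0
    for pop, w in (("reference", weight_ref), ("contrast", weight_con)):
        frac = w / w.sum()
        prefix = "ref" if pop == "reference" else "con"
        for c in range(1, n_cells + 1):
            rng = np.random.default_rng(children[k])
            depth = float(_lognormal(rng, depth_mean, depth_cv))
            col = sample_negative_binomial(rng, depth * frac, dispersion)
            if dropout_extra > 0:
                col = col * (rng.random(n_genes) >= dropout_extra)
            counts[:, k] = col
            cell_ids.append(f"{prefix}_{c:05d}")
            pops.append(pop)
            k += 1
    labels = pd.Series(pops, index=pd.Index(cell_ids, name="cell_id"), name="population")
    return CountMatrix(list(gene_ids), cell_ids, counts), labels


def simulate_sc(p: ScSimParams) -> tuple[CountMatrix, pd.Series, pd.DataFrame]:
    """Simulate a two-population single-cell count matrix with planted markers.

    Markers are elevated ``marker_fold``-fold in the reference population.
    Returns ``(counts, cell population labels, ground truth)``.
    """
    p.validate()
    root = np.random.SeedSequence(p.seed)
    gene_child, cells_child = root.spawn(2)
    rng = np.random.default_rng(gene_child)
    gene_ids = _gene_ids(p.n_genes)
    labels = np.array(["null"] * p.n_genes, dtype=object)
    perm = rng.permutation(p.n_genes)
    labels[perm[: p.n_planted_markers]] = "marker"
    weights = _log_uniform(rng, *p.baseline_weight_range, p.n_genes)
    is_marker = labels == "marker"
    weights[is_marker] = _log_uniform(rng, *p.marker_weight_range, int(is_marker.sum()))
    w_ref = weights.copy()
    w_ref[is_marker] *= p.marker_fold
    cm, cell_labels = _simulate_two_populations(
        gene_ids,
        w_ref,
        weights,
        p.n_cells_per_population,
        p.capture_depth_mean,
        p.depth_cv,
        p.dispersion,
        p.dropout_extra,
        cells_child,
    )
    truth = pd.DataFrame({"gene_id": gene_ids, "label": labels})
    return cm, cell_labels, truth


@dataclass
class ShiftSimData:
    """Paired datasets for the developmental-shift analysis, with ground truth."""

    sc_counts: CountMatrix
    cell_labels: pd.Series
    bulk_counts: CountMatrix
    bulk_sheet: pd.DataFrame
    truth: pd.DataFrame

    @property
    def tg_columns(self) -> list[str]:
        return list(self.bulk_sheet.loc[self.bulk_sheet["process"] == "tg", "column_id"])

    @property
    def control_columns(self) -> list[str]:
        return list(
            self.bulk_sheet.loc[self.bulk_sheet["process"] == "control", "column_id"]
        )


def simulate_shift_pair(p: ShiftSimParams) -> ShiftSimData:
    """Simulate the reference single-cell contrast and the Tg-vs-control bulk.

    Every common gene is differential in both contrasts; with probability
    ``concordance_rate`` its transgenic direction matches its
    reference-over-contrast (developmental) direction, otherwise it opposes
    it.  Ground truth labels each gene concordant / discordant / null and
    records both planted directions.
    """
    p.validate()
    n_total = p.n_common_genes + p.n_null_genes
    root = np.random.SeedSequence(p.seed)
    gene_child, sc_child, bulk_child = root.spawn(3)
    rng = np.random.default_rng(gene_child)

    gene_ids = _gene_ids(n_total)
    common = np.zeros(n_total, dtype=bool)
    common[rng.permutation(n_total)[: p.n_common_genes]] = True

    weights = _log_uniform(rng, *p.null_weight_range, n_total)
    weights[common] = _log_uniform(rng, *p.common_weight_range, p.n_common_genes)

    d_sc = np.zeros(n_total, dtype=int)
    d_sc[common] = rng.choice([-1, 1], p.n_common_genes)
    concordant = np.zeros(n_total, dtype=bool)
    concordant[common] = rng.random(p.n_common_genes) < p.concordance_rate
    d_tg = np.where(concordant, d_sc, -d_sc)
    d_tg[~common] = 0

    w_ref = weights * np.where(d_sc > 0, p.marker_fold, 1.0)
    w_con = weights * np.where(d_sc < 0, p.marker_fold, 1.0)
    sc_counts, cell_labels = _simulate_two_populations(
        gene_ids,
        w_ref,
        w_con,
        p.n_cells_per_population,
        p.capture_depth_mean,
        0.3,
        p.sc_dispersion,
        p.dropout_extra,
        sc_child,
    )

    bulk_fold = 2.0**p.tg_effect_log2
    w_tg = weights * np.where(d_tg > 0, bulk_fold, 1.0)
    w_ctrl = weights * np.where(d_tg < 0, bulk_fold, 1.0)
    children = bulk_child.spawn(2 * p.n_replicates)
    counts = np.empty((n_total, 2 * p.n_replicates), dtype=np.int64)
    rows = []
    k = 0
    for process, w in (("tg", w_tg), ("control", w_ctrl)):
        frac = w / w.sum()
        for rep in range(1, p.n_replicates + 1):
            col_rng = np.random.default_rng(children[k])
            libsize = float(_lognormal(col_rng, p.library_size_mean, p.library_size_cv))
            counts[:, k] = sample_negative_binomial(col_rng, libsize * frac, p.bulk_dispersion)
            rows.append(
                {
                    "column_id": f"{process}_r{rep}",
                    "process": process,
                    "axis": "na",
                    "timepoint": 1,
                    "replicate": rep,
                }
            )
            k += 1
    sheet = pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS)
    bulk = CountMatrix(gene_ids, list(sheet["column_id"]), counts)

    label = np.where(common, np.where(concordant, "concordant", "discordant"), "null")
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "label": label,
            "reference_direction": d_sc,
            "tg_direction": d_tg,
        }
    )
    return ShiftSimData(sc_counts, cell_labels, bulk, sheet, truth)
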