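"""Core data containers and the fixed development/regeneration study layout.

The study design compares limb *development* (distal/proximal tissue at four
stages: devD1..devD4, devP1..devP4) with larval *regeneration* (distal =
blastema, proximal = stump, at two stages: regD1, regD2, regP1, regP2), twelve
conditions in total, each sequenced in replicate.  Each regeneration sample is
matched to the developmental sample with the most similar tissue stage and
shape — the four *corresponding pairs* regD1/devD1, regD2/devD2, regP1/devP3
and regP2/devP4.  Note that the proximal pairs are matched by tissue
similarity, not by timepoint index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

PROCESSES = ("development", "regeneration", "tg", "control")
AXES = ("distal", "proximal", "na")
EXPRESSION_UNITS = ("tpm", "cpm", "log2_tpm_plus1", "zscore")

_PROCESS_SHORT = {"development": "dev", "regeneration": "reg"}
_AXIS_SHORT = {"distal": "D", "proximal": "P"}


@dataclass(frozen=True, order=True)
class Condition:
    """One (process, axis, timepoint) cell of the bulk design."""

    process: str
    axis: str
    timepoint: int

    def __post_init__(self) -> None:
        if self.process not in PROCESSES:
            raise ValueError(f"unknown process {self.process!r}")
        if self.axis not in AXES:
            raise ValueError(f"unknown axis {self.axis!r}")
        if self.timepoint < 1:
            raise ValueError("timepoint index must be >= 1")

    @property
    def label(self) -> str:
        """Compact label, e.g. ``regD1`` or ``devP3``."""
        if self.process in _PROCESS_SHORT and self.axis in _AXIS_SHORT:
            return f"{_PROCESS_SHORT[self.process]}{_AXIS_SHORT[self.axis]}{self.timepoint}"
        return f"{self.process}{self.timepoint}"

    @property
    def long_name(self) -> str:
        """Verbose name used in error messages, e.g. ``regeneration/distal/t2``."""
        return f"{self.process}/{self.axis}/t{self.timepoint}"


def condition_from_label(label: str) -> Condition:
    """Parse a compact condition label such as ``devP3`` back to a Condition."""
    for proc, p in _PROCESS_SHORT.items():
        for axis, a in _AXIS_SHORT.items():
            prefix = p + a
            if label.startswith(prefix):
                return Condition(proc, axis, int(label[len(prefix):]))
    raise ValueError(f"cannot parse condition label {label!r}")


@dataclass(frozen=True)
class StudyDesign:
    """The fixed 12-condition development/regeneration layout.

    Attributes
    ----------
    conditions
        All conditions in the design.
    corresponding_pairs
        ``(regeneration condition, development condition)`` tuples matched by
        tissue stage/shape similarity.
    reg_distal_conditions, dev_distal_conditions
        The distal (blastema / limb-bud) conditions entering the
        regeneration-specificity score.
    """

    conditions: tuple[Condition, ...]
    corresponding_pairs: tuple[tuple[Condition, Condition], ...]
    reg_distal_conditions: tuple[Condition, ...]
    dev_distal_conditions: tuple[Condition, ...]

    @property
    def max_score(self) -> int:
        """Maximum attainable regeneration-specificity score (2 x 4 = 8 by default)."""
        return len(self.reg_distal_conditions) * len(self.dev_distal_conditions)


def default_design() -> StudyDesign:
    """Return the standard 12-condition design with its four corresponding pairs."""
    dev = {
        (axis, t): Condition("development", axis, t)
        for axis in ("distal", "proximal")
        for t in range(1, 5)
    }
    reg = {
        (axis, t): Condition("regeneration", axis, t)
        for axis in ("distal", "proximal")
        for t in range(1, 3)
    }
    conditions = tuple(dev.values()) + tuple(reg.values())
    pairs = (
        (reg[("distal", 1)], dev[("distal", 1)]),
        (reg[("distal", 2)], dev[("distal", 2)]),
        (reg[("proximal", 1)], dev[("proximal", 3)]),
        (reg[("proximal", 2)], dev[("proximal", 4)]),
    )
    return StudyDesign(
        conditions=conditions,
        corresponding_pairs=pairs,
        reg_distal_conditions=(reg[("distal", 1)], reg[("distal", 2)]),
        dev_distal_conditions=tuple(dev[("distal", t)] for t in range(1, 5)),
    )


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dup = set(), set()
        for i in ids:
            (dup if i in seen else seen).add(i)
        raise ValueError(f"duplicate {what}: {sorted(dup)[:5]}")
    return ids


@dataclass
class CountMatrix:
    """Integer gene x sample (or gene x cell) read counts.

    ``gene_lengths`` (nucleotides) are optional and only required for TPM.
    """

    gene_ids: list[str]
    column_ids: list[str]
    counts: np.ndarray
    gene_lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene_ids")
        self.column_ids = _check_unique(self.column_ids, "column_ids")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.gene_ids), len(self.column_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.column_ids)} columns)"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)):
                raise ValueError("counts must be finite")
            rounded = np.rint(counts)
            if not np.array_equal(rounded, counts):
                raise ValueError("counts must be integers")
            counts = rounded.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(np.int64, copy=False)
        if self.gene_lengths is not None:
            lengths = np.asarray(self.gene_lengths, dtype=float)
            if lengths.shape != (len(self.gene_ids),):
                raise ValueError("gene_lengths must align with gene_ids")
            if not np.all(np.isfinite(lengths)) or np.any(lengths <= 0):
                raise ValueError("gene_lengths must be finite and > 0")
            self.gene_lengths = lengths

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_columns(self) -> int:
        return len(self.column_ids)

    def column_indices(self, ids: Sequence[str]) -> np.ndarray:
        pos = {c: i for i, c in enumerate(self.column_ids)}
        missing = [c for c in ids if c not in pos]
        if missing:
            raise KeyError(f"columns not in matrix: {missing}")
        return np.array([pos[c] for c in ids], dtype=int)

    def select_columns(self, ids: Sequence[str]) -> np.ndarray:
        """Counts restricted to the named columns (genes x len(ids))."""
        return self.counts[:, self.column_indices(ids)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.column_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, gene_lengths=None) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(), gene_lengths)


@dataclass
class ExpressionMatrix:
    """Normalized expression values with the unit recorded.

    tpm/cpm columns sum to 1e6 (relative tolerance 1e-9); all-zero columns are
    permitted (they arise from empty libraries and are preserved as zeros).
    """

    gene_ids: list[str]
    column_ids: list[str]
    values: np.ndarray
    unit: str

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene_ids")
        self.column_ids = _check_unique(self.column_ids, "column_ids")
        if self.unit not in EXPRESSION_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {EXPRESSION_UNITS}")
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.gene_ids), len(self.column_ids)):
            raise ValueError("values shape does not match identifiers")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")
        self.values = values
        if self.unit in ("tpm", "cpm") and values.size:
            sums = values.sum(axis=0)
            nonzero = sums > 0
            if np.any(np.abs(sums[nonzero] - 1e6) > 1e-9 * 1e6):
                raise ValueError(f"{self.unit} columns must sum to 1e6")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def column_indices(self, ids: Sequence[str]) -> np.ndarray:
        pos = {c: i for i, c in enumerate(self.column_ids)}
        missing = [c for c in ids if c not in pos]
        if missing:
            raise KeyError(f"columns not in matrix: {missing}")
        return np.array([pos[c] for c in ids], dtype=int)

    def gene_indices(self, ids: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in ids if g not in pos]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return np.array([pos[g] for g in ids], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.column_ids)


def aggregate_homeologs(
    m: CountMatrix | ExpressionMatrix, mapping: Mapping[str, str]
) -> CountMatrix | ExpressionMatrix:
    """Sum rows that share a homeolog group id.

    In the allotetraploid *X. laevis* genome most genes exist as .L/.S
    subgenome copies; gene-level expression is the sum of the two homeologs.
    ``mapping`` sends gene ids to group ids; unmapped genes pass through under
    their own id.  Row order follows first occurrence.  The grand total of the
    matrix is conserved exactly (integer input) or to floating precision.
    """
    new_ids: list[str] = []
    seen: dict[str, int] = {}
    mapped_targets = set()
    passthrough = set()
    rows: list[list[int]] = []
    for i, g in enumerate(m.gene_ids):
        target = mapping.get(g, g)
        if g in mapping:
            mapped_targets.add(target)
        else:
            passthrough.add(target)
        if target in seen:
            rows[seen[target]].append(i)
        else:
            seen[target] = len(new_ids)
            new_ids.append(target)
            rows.append([i])
    clash = mapped_targets & passthrough
    if clash:
        raise ValueError(
            f"homeolog group ids collide with existing gene ids: {sorted(clash)[:5]}"
        )
    data = m.counts if isinstance(m, CountMatrix) else m.values
    out = np.empty((len(new_ids), data.shape[1]), dtype=data.dtype)
    for j, idx in enumerate(rows):
        out[j] = data[idx].sum(axis=0)
    if isinstance(m, CountMatrix):
        return CountMatrix(new_ids, list(m.column_ids), out, gene_lengths=None)
    return ExpressionMatrix(new_ids, list(m.column_ids), out, m.unit)


SAMPLE_SHEET_COLUMNS = ["column_id", "process", "axis", "timepoint", "replicate"]


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet and return it with canonical dtypes.

    Required columns: column_id, process, axis, timepoint, replicate.
    (process, axis, timepoint, replicate) must be unique.
    """
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    sheet = sheet[SAMPLE_SHEET_COLUMNS].copy()
    sheet["column_id"] = sheet["column_id"].astype(str)
    sheet["timepoint"] = sheet["timepoint"].astype(int)
    sheet["replicate"] = sheet["replicate"].astype(int)
    bad = ~sheet["process"].isin(PROCESSES)
    if bad.any():
        raise ValueError(f"unknown process values: {sorted(sheet.loc[bad, 'process'].unique())}")
    bad = ~sheet["axis"].isin(AXES)
    if bad.any():
        raise ValueError(f"unknown axis values: {sorted(sheet.loc[bad, 'axis'].unique())}")
    if (sheet["timepoint"] < 1).any() or (sheet["replicate"] < 1).any():
        raise ValueError("timepoint and replicate indices must be >= 1")
    key = sheet[["process", "axis", "timepoint", "replicate"]]
    if key.duplicated().any():
        raise ValueError("duplicate (process, axis, timepoint, replicate) in sample sheet")
    if sheet["column_id"].duplicated().any():
        raise ValueError("duplicate column_id in sample sheet")
    return sheet


def columns_for_condition(sheet: pd.DataFrame, cond: Condition) -> list[str]:
    """Column ids of all replicates of one condition, in replicate order."""
    sel = sheet[
        (sheet["process"] == cond.process)
        & (sheet["axis"] == cond.axis)
        & (sheet["timepoint"] == cond.timepoint)
    ].sort_values("replicate")
    return list(sel["column_id"])


def check_design_columns(
    sheet: pd.DataFrame, design: StudyDesign, min_replicates: int = 2
) -> dict[Condition, list[str]]:
    """Map each design condition to its columns, raising on missing/underpowered ones."""
    out: dict[Condition, list[str]] = {}
    problems = []
    for cond in design.conditions:
        cols = columns_for_condition(sheet, cond)
        if len(cols) < min_replicates:
            problems.append(f"{cond.long_name} ({len(cols)} replicate(s))")
        out[cond] = cols
    if problems:
        raise ValueError(
            "sample sheet is missing replicates for condition(s): " + "; ".join(problems)
        )
    return out
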