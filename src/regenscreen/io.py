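"""Plain-text IO: counts TSV, sample sheets, homeolog maps, Matrix Market trios.

One fixed dialect: tab-separated, header row, first column ``gene_id``, UTF-8,
no quoting.  Sparse single-cell matrices use 1-based Matrix Market coordinate
triplets with companion ``features.tsv`` (gene ids) and ``cells.tsv``
(cell_id, population).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import CountMatrix, ExpressionMatrix, validate_sample_sheet


def _read_tsv(path, **kw) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path, sep="\t", **kw)
    except Exception as exc:  # re-raise naming the file
        raise ValueError(f"{path}: cannot parse TSV ({exc})") from exc


def read_counts_tsv(path, lengths_path=None) -> CountMatrix:
    """Read a gene x sample counts TSV (first column gene_id)."""
    df = _read_tsv(path, index_col=0)
    if df.index.name != "gene_id":
        raise ValueError(f"{path}: first column must be named 'gene_id'")
    lengths = None
    if lengths_path is not None:
        lengths = read_lengths_tsv(lengths_path).reindex(df.index)
        if lengths.isna().any():
            missing = list(lengths.index[lengths.isna()])[:5]
            raise ValueError(f"{lengths_path}: missing lengths for genes {missing}")
        lengths = lengths.to_numpy()
    return CountMatrix(list(df.index), list(df.columns), df.to_numpy(), lengths)


def write_counts_tsv(cm: CountMatrix, path) -> None:
    df = cm.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_lengths_tsv(path) -> pd.Series:
    """Two-column TSV ``gene_id length`` -> Series indexed by gene."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns gene_id and length")
    return df.set_index(df.columns[0])[df.columns[1]].astype(float)


def write_lengths_tsv(cm: CountMatrix, path) -> None:
    if cm.gene_lengths is None:
        raise ValueError("count matrix has no gene lengths")
    pd.DataFrame({"gene_id": cm.gene_ids, "length": cm.gene_lengths}).to_csv(
        path, sep="\t", index=False
    )


def read_sample_sheet(path) -> pd.DataFrame:
    return validate_sample_sheet(_read_tsv(path))


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    validate_sample_sheet(sheet).to_csv(path, sep="\t", index=False)


def read_homeolog_map(path) -> dict[str, str]:
    """Two-column TSV ``gene_id group_id`` -> mapping dict."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns gene_id and group_id")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_expression_tsv(m: ExpressionMatrix, path) -> None:
    df = m.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def write_sc_mtx(cm: CountMatrix, labels: pd.Series, out_dir) -> None:
    """Write matrix.mtx + features.tsv + cells.tsv for a labelled cell matrix."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(
        str(out / "matrix.mtx"), sparse.coo_matrix(cm.counts), field="integer"
    )
    pd.DataFrame({"gene_id": cm.gene_ids}).to_csv(
        out / "features.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {"cell_id": cm.column_ids, "population": labels.reindex(cm.column_ids).to_numpy()}
    ).to_csv(out / "cells.tsv", sep="\t", index=False)


def read_sc_mtx(matrix_path, features_path=None, cells_path=None):
    """Read a Matrix Market trio back to (CountMatrix, population labels)."""
    matrix_path = Path(matrix_path)
    if features_path is None:
        features_path = matrix_path.parent / "features.tsv"
    if cells_path is None:
        cells_path = matrix_path.parent / "cells.tsv"
    try:
        mat = spio.mmread(str(matrix_path))
    except Exception as exc:
        raise ValueError(f"{matrix_path}: cannot parse Matrix Market file ({exc})") from exc
    genes = list(_read_tsv(features_path)["gene_id"].astype(str))
    cells = _read_tsv(cells_path)
    if "cell_id" not in cells.columns:
        raise ValueError(f"{cells_path}: expected a cell_id column")
    dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
    cm = CountMatrix(genes, list(cells["cell_id"].astype(str)), dense)
    labels = None
    if "population" in cells.columns:
        labels = pd.Series(
            cells["population"].to_numpy(),
            index=pd.Index(cells["cell_id"].astype(str), name="cell_id"),
            name="population",
        )
    return cm, labels


def read_truth_tsv(path) -> pd.DataFrame:
    return _read_tsv(path)


def write_json(obj: Mapping, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
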