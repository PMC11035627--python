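import numpy as np
import pandas as pd
import pytest

from regenscreen.containers import default_design
from regenscreen.simulate import (
    BulkSimParams,
    ScSimParams,
    simulate_bulk,
    simulate_sc,
)


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def small_bulk(design):
    """Small bulk dataset with a handful of planted genes of every class."""
    params = BulkSimParams(
        n_genes=400,
        n_planted_regspecific=8,
        n_planted_distal_shared=10,
        n_planted_proximal=10,
        seed=11,
    )
    counts, sheet, truth = simulate_bulk(design, params)
    return counts, sheet, truth


@pytest.fixture(scope="session")
def small_sc():
    """Two-population single-cell dataset with planted markers."""
    params = ScSimParams(
        n_genes=800,
        n_cells_per_population=250,
        n_planted_markers=40,
        marker_fold=4.0,
        seed=5,
    )
    counts, labels, truth = simulate_sc(params)
    return counts, labels, truth


@pytest.fixture
def tpm_matrix():
    """Deterministic random TPM matrix builder (columns rescaled to 1e6)."""

    def build(n_genes, column_ids, seed=0, gene_ids=None):
        from regenscreen.containers import ExpressionMatrix

        rng = np.random.default_rng(seed)
        vals = rng.uniform(0.1, 100.0, (n_genes, len(column_ids)))
        vals = vals / vals.sum(axis=0) * 1e6
        if gene_ids is None:
            gene_ids = [f"g{i:04d}" for i in range(n_genes)]
        return ExpressionMatrix(gene_ids, list(column_ids), vals, "tpm")

    return build


def bulk_sheet_columns(sheet: pd.DataFrame, label: str) -> list[str]:
    from regenscreen.containers import columns_for_condition, condition_from_label

    return columns_for_condition(sheet, condition_from_label(label))
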