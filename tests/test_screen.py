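import numpy as np
import pandas as pd
import pytest

from regenscreen.containers import (
    CountMatrix,
    ExpressionMatrix,
    columns_for_condition,
    default_design,
)
from regenscreen.screen import (
    run_screen_pipeline,
    screen1_corresponding_pairs,
    screen2_distal_over_proximal,
    specificity_score,
)
from regenscreen.simulate import BulkSimParams, simulate_bulk


def _design_sheet(n_rep=3):
    design = default_design()
    rows = []
    for cond in design.conditions:
        for r in range(1, n_rep + 1):
            rows.append(
                {
                    "column_id": f"{cond.label}_r{r}",
                    "process": cond.process,
                    "axis": cond.axis,
                    "timepoint": cond.timepoint,
                    "replicate": r,
                }
            )
    return design, pd.DataFrame(rows)


def _flat_counts(n_genes=30, n_rep=3, base=200, seed=0):
    """Counts with no structure at all: every column iid around `base`."""
    design, sheet = _design_sheet(n_rep)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(base, (n_genes, len(sheet)))
    cm = CountMatrix(
        [f"g{i:03d}" for i in range(n_genes)],
        list(sheet["column_id"]),
        counts,
        gene_lengths=np.full(n_genes, 1000.0),
    )
    return cm, sheet, design


def _boost(cm, sheet, gene, labels, factor):
    """Multiply one gene's counts in the named conditions."""
    from regenscreen.containers import condition_from_label

    cols = [
        c
        for lab in labels
        for c in columns_for_condition(sheet, condition_from_label(lab))
    ]
    counts = cm.counts.copy()
    gi = cm.gene_ids.index(gene)
    ci = cm.column_indices(cols)
    counts[gi, ci] = counts[gi, ci] * factor
    return CountMatrix(cm.gene_ids, cm.column_ids, counts, cm.gene_lengths)


class TestScreen1:
    def test_single_pair_effect_included_via_union(self):
        cm, sheet, design = _flat_counts()
        cm = _boost(cm, sheet, "g005", ["regD1"], 8)
        hits = screen1_corresponding_pairs(cm, sheet, design)
        assert "g005" in hits

    def test_flat_gene_excluded(self):
        cm, sheet, design = _flat_counts()
        hits = screen1_corresponding_pairs(cm, sheet, design, alpha=1e-4)
        assert "g000" not in hits

    def test_all_rule_stricter_than_union(self):
        cm, sheet, design = _flat_counts()
        cm = _boost(cm, sheet, "g005", ["regD1"], 8)
        union = set(screen1_corresponding_pairs(cm, sheet, design, rule="union"))
        both = set(screen1_corresponding_pairs(cm, sheet, design, rule="all"))
        assert both <= union and "g005" not in both

    def test_missing_condition_error_names_it(self):
        cm, sheet, design = _flat_counts()
        broken = sheet[sheet["column_id"] != "regD2_r1"]
        broken = broken[broken["column_id"] != "regD2_r2"]
        broken = broken[broken["column_id"] != "regD2_r3"]
        with pytest.raises(ValueError, match="regeneration/distal/t2"):
            screen1_corresponding_pairs(cm, broken, design)


class TestScreen2:
    def test_direction_requirement(self):
        cm, sheet, design = _flat_counts()
        cm = _boost(cm, sheet, "g003", ["regP1", "regP2"], 8)  # proximal-biased
        cm = _boost(cm, sheet, "g004", ["regD1", "regD2"], 8)  # distal-biased
        hits = screen2_distal_over_proximal(cm, sheet, ["g003", "g004"], design)
        assert "g004" in hits and "g003" not in hits

    def test_untested_gene_rejected(self):
        cm, sheet, design = _flat_counts()
        with pytest.raises(ValueError, match="untested"):
            screen2_distal_over_proximal(cm, sheet, ["nope"], design)


def _tpm_from_condition_means(means, design, n_rep=1):
    """Build a TPM matrix whose replicate means per condition are exact."""
    _, sheet = _design_sheet(n_rep)
    cols = list(sheet["column_id"])
    n_genes = len(next(iter(means.values())))
    vals = np.zeros((n_genes + 1, len(cols)))
    for j, c in enumerate(cols):
        lab = c.rsplit("_", 1)[0]
        vals[:-1, j] = means.get(lab, np.zeros(n_genes))
    # filler gene absorbs the remainder so columns sum to 1e6 (valid TPM)
    vals[-1] = 1e6 - vals[:-1].sum(axis=0)
    genes = [f"g{i:03d}" for i in range(n_genes)] + ["filler"]
    return ExpressionMatrix(genes, cols, vals, "tpm"), sheet


class TestSpecificityScore:
    def test_dominating_gene_scores_eight(self, design):
        means = {lab: np.array([100.0]) for lab in
                 ["devD1", "devD2", "devD3", "devD4", "devP1", "devP2", "devP3",
                  "devP4", "regP1", "regP2"]}
        means["regD1"] = np.array([900.0])
        means["regD2"] = np.array([900.0])
        expr, sheet = _tpm_from_condition_means(means, design)
        out = specificity_score(expr, sheet, ["g000"], design)
        assert out.loc[0, "score"] == 8

    def test_all_equal_means_score_zero(self, design):
        means = {lab: np.array([100.0]) for lab in
                 ["devD1", "devD2", "devD3", "devD4", "regD1", "regD2",
                  "devP1", "devP2", "devP3", "devP4", "regP1", "regP2"]}
        expr, sheet = _tpm_from_condition_means(means, design)
        out = specificity_score(expr, sheet, ["g000"], design)
        assert out.loc[0, "score"] == 0

    def test_matches_double_loop_oracle(self, design):
        rng = np.random.default_rng(8)
        n = 200
        means = {lab: rng.uniform(10, 500, n) for lab in
                 ["devD1", "devD2", "devD3", "devD4", "regD1", "regD2"]}
        for lab in ["devP1", "devP2", "devP3", "devP4", "regP1", "regP2"]:
            means[lab] = rng.uniform(10, 500, n)
        expr, sheet = _tpm_from_condition_means(means, design)
        genes = [f"g{i:03d}" for i in range(n)]
        out = specificity_score(expr, sheet, genes, design).set_index("gene_id")
        for i, g in enumerate(genes):
            expected = 0
            for r in ("regD1", "regD2"):
                for d in ("devD1", "devD2", "devD3", "devD4"):
                    if means[r][i] > means[d][i]:
                        expected += 1
            assert out.loc[g, "score"] == expected

    def test_rank_tie_breaking_is_deterministic(self, design):
        # two genes, identical scores and margins -> lexicographic order
        means = {lab: np.array([100.0, 100.0]) for lab in
                 ["devD1", "devD2", "devD3", "devD4", "devP1", "devP2", "devP3",
                  "devP4", "regP1", "regP2"]}
        means["regD1"] = np.array([300.0, 300.0])
        means["regD2"] = np.array([300.0, 300.0])
        expr, sheet = _tpm_from_condition_means(means, design)
        out = specificity_score(expr, sheet, ["g001", "g000"], design)
        assert list(out["gene_id"]) == ["g000", "g001"]

    def test_monotone_in_regeneration_expression(self, design):
        rng = np.random.default_rng(9)
        labs = ["devD1", "devD2", "devD3", "devD4", "regD1", "regD2",
                "devP1", "devP2", "devP3", "devP4", "regP1", "regP2"]
        means = {lab: rng.uniform(10, 500, 20) for lab in labs}
        expr, sheet = _tpm_from_condition_means(means, design)
        genes = [f"g{i:03d}" for i in range(20)]
        base = specificity_score(expr, sheet, genes, design).set_index("gene_id")["score"]
        means2 = {k: v.copy() for k, v in means.items()}
        means2["regD1"] = means2["regD1"] + 100.0  # raise regeneration expression
        expr2, sheet2 = _tpm_from_condition_means(means2, design)
        bumped = specificity_score(expr2, sheet2, genes, design).set_index("gene_id")["score"]
        assert (bumped.sort_index() >= base.sort_index()).all()


class TestPipeline:
    def test_nesting_and_planted_recovery(self, small_bulk, design):
        counts, sheet, truth = small_bulk
        res = run_screen_pipeline(counts, sheet, design, top=10)
        assert set(res.scored["gene_id"]) == set(res.screen2_genes)
        assert set(res.screen2_genes) <= set(res.screen1_genes)
        assert set(res.screen1_genes) <= set(counts.gene_ids)
        planted = set(truth.loc[truth["label"] == "regspecific", "gene_id"])
        recovered = planted & set(res.top_by_score(len(planted) + 5))
        assert len(recovered) >= 0.75 * len(planted)
        proximal = set(truth.loc[truth["label"] == "proximal", "gene_id"])
        assert not (proximal & set(res.screen2_genes))

    def test_empty_result_warns_and_returns_empty_table(self):
        cm, sheet, design = _flat_counts(n_genes=15, base=500)
        with pytest.warns(UserWarning, match="no genes survive"):
            res = run_screen_pipeline(cm, sheet, design, alpha=1e-12)
        assert res.scored.empty and res.top_genes == []
        assert len(res.table) == cm.n_genes

    def test_tpm_scale_invariance_of_scores(self, small_bulk, design):
        counts, sheet, _ = small_bulk
        res1 = run_screen_pipeline(counts, sheet, design)
        doubled = CountMatrix(
            counts.gene_ids, counts.column_ids, counts.counts * 2, counts.gene_lengths
        )
        res2 = run_screen_pipeline(doubled, sheet, design)
        merged = res1.scored.merge(res2.scored, on="gene_id", suffixes=("_1", "_2"))
        # scores depend on TPM only, which is invariant to per-column scaling
        assert (merged["score_1"] == merged["score_2"]).all()

    def test_max_score_group_selection(self, small_bulk, design):
        counts, sheet, _ = small_bulk
        res = run_screen_pipeline(counts, sheet, design)
        if not res.scored.empty:
            best = res.scored["score"].max()
            assert set(res.max_score_group()) == set(
                res.scored.loc[res.scored["score"] == best, "gene_id"]
            )
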