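import numpy as np
import pandas as pd
import pytest

from regenscreen.containers import CountMatrix
from regenscreen.models import DevelopmentalShiftModel
from regenscreen.shift import (
    bulk_deg_tg,
    sc_find_markers,
    shift_consistency,
    zscore_profiles,
)
from regenscreen.simulate import ShiftSimParams, simulate_shift_pair


class TestScFindMarkers:
    def test_planted_marker_recovery(self, small_sc):
        counts, labels, truth = small_sc
        res = sc_find_markers(counts, labels)
        planted = truth["label"].to_numpy() == "marker"
        recall = res.loc[planted, "passes"].mean()
        assert recall >= 0.9
        # planted markers are elevated in the reference population
        assert (res.loc[planted & res["passes"].to_numpy(), "log2fc"] > 0).all()

    def test_permutation_null_passes_few(self, small_sc):
        counts, labels, _ = small_sc
        rng = np.random.default_rng(0)
        rates = []
        for _ in range(5):
            shuffled = pd.Series(
                rng.permutation(labels.to_numpy()), index=labels.index, name="population"
            )
            res = sc_find_markers(counts, shuffled)
            rates.append(res["passes"].mean())
        assert max(rates) <= 0.01

    def test_never_expressed_gene_fails(self, small_sc):
        counts, labels, _ = small_sc
        zeroed = counts.counts.copy()
        zeroed[0] = 0
        cm = CountMatrix(counts.gene_ids, counts.column_ids, zeroed)
        res = sc_find_markers(cm, labels)
        assert not res.loc[0, "passes"]
        assert res.loc[0, "p"] == 1.0 and res.loc[0, "fdr"] == 1.0

    def test_pct_rule_both_vs_either(self, small_sc):
        counts, labels, _ = small_sc
        both = sc_find_markers(counts, labels, pct_rule="both")
        either = sc_find_markers(counts, labels, pct_rule="either")
        assert set(both.loc[both["passes"], "gene_id"]) <= set(
            either.loc[either["passes"], "gene_id"]
        )

    def test_single_population_rejected(self, small_sc):
        counts, labels, _ = small_sc
        only_ref = pd.Series("reference", index=labels.index, name="population")
        with pytest.raises(ValueError, match="non-empty"):
            sc_find_markers(counts, only_ref)


class TestZscoreProfiles:
    def test_pooled_zero_identity(self, small_sc):
        counts, labels, _ = small_sc
        prof = zscore_profiles(counts, labels, n_per_pop=200, seed=1)
        total = (
            prof.attrs["n_ref"] * prof["mean_z_reference"]
            + prof.attrs["n_con"] * prof["mean_z_contrast"]
        )
        np.testing.assert_allclose(total, 0.0, atol=1e-9)

    def test_equal_subsamples_mirror(self, small_sc):
        counts, labels, _ = small_sc
        prof = zscore_profiles(counts, labels, n_per_pop=100, seed=2)
        np.testing.assert_allclose(
            prof["mean_z_reference"], -prof["mean_z_contrast"], atol=1e-9
        )

    def test_planted_markers_positive_in_reference(self, small_sc):
        counts, labels, truth = small_sc
        prof = zscore_profiles(counts, labels, n_per_pop=250, seed=3)
        planted = truth["label"].to_numpy() == "marker"
        assert (prof.loc[planted, "mean_z_reference"] > 0).mean() >= 0.95

    def test_small_population_warns_and_uses_all(self, small_sc):
        counts, labels, _ = small_sc
        with pytest.warns(UserWarning, match="using all"):
            prof = zscore_profiles(counts, labels, n_per_pop=10_000, seed=0)
        assert prof.attrs["n_ref"] == (labels == "reference").sum()

    def test_constant_gene_maps_to_zero(self, small_sc):
        counts, labels, _ = small_sc
        zeroed = counts.counts.copy()
        zeroed[5] = 0
        cm = CountMatrix(counts.gene_ids, counts.column_ids, zeroed)
        prof = zscore_profiles(cm, labels, n_per_pop=100, seed=0)
        assert prof.loc[5, "mean_z_reference"] == 0.0
        assert prof.loc[5, "mean_z_contrast"] == 0.0


class TestBulkDegTg:
    def test_identical_arms_select_nothing(self):
        rng = np.random.default_rng(4)
        counts = rng.negative_binomial(10, 0.05, (100, 4))
        cm = CountMatrix(
            [f"g{i}" for i in range(100)],
            [f"tg_r{i}" for i in range(4)] + [f"ctrl_r{i}" for i in range(4)],
            np.hstack([counts, counts]),
        )
        res = bulk_deg_tg(cm, cm.column_ids[:4], cm.column_ids[4:])
        assert not res["selected"].any()

    def test_direction_flips_when_arms_swapped(self):
        rng = np.random.default_rng(5)
        a = rng.negative_binomial(10, 0.05, (50, 4))
        b = a.copy()
        b[:10] *= 6
        cm = CountMatrix(
            [f"g{i}" for i in range(50)],
            [f"c{i}" for i in range(8)],
            np.hstack([a, b]),
        )
        fwd = bulk_deg_tg(cm, cm.column_ids[4:], cm.column_ids[:4])
        rev = bulk_deg_tg(cm, cm.column_ids[:4], cm.column_ids[4:])
        sel = fwd["selected"] & rev["selected"]
        assert sel.any()
        assert (fwd.loc[sel, "direction"] == -rev.loc[sel, "direction"]).all()


class TestShiftConsistency:
    @staticmethod
    def _tables(directions_ref, directions_tg):
        n = len(directions_ref)
        genes = [f"g{i}" for i in range(n)]
        markers = pd.DataFrame(
            {"gene_id": genes, "log2fc": np.asarray(directions_ref, dtype=float) * 2.0,
             "passes": True}
        )
        tg = pd.DataFrame(
            {"gene_id": genes, "log2fc": np.asarray(directions_tg, dtype=float),
             "direction": np.sign(directions_tg).astype(int), "selected": True}
        )
        return markers, tg

    def test_full_agreement_gives_one(self):
        markers, tg = self._tables([1, -1, 1], [1, -1, 1])
        assert shift_consistency(markers, tg).concordance_fraction == 1.0

    def test_empty_common_set_is_undefined(self):
        markers, tg = self._tables([1], [1])
        markers["passes"] = False
        with pytest.warns(UserWarning, match="undefined"):
            rep = shift_consistency(markers, tg)
        assert rep.concordance_fraction is None

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(6)
        d_ref = rng.choice([-1, 1], 40)
        d_tg = rng.choice([-1, 1], 40)
        markers, tg = self._tables(d_ref, d_tg)
        base = shift_consistency(markers, tg).concordance_fraction
        perm = rng.permutation(40)
        shuffled = shift_consistency(
            markers.iloc[perm].reset_index(drop=True), tg.iloc[perm].reset_index(drop=True)
        ).concordance_fraction
        assert base == shuffled

    def test_joint_relabel_invariance(self):
        # flipping both contrasts' directions together leaves concordance unchanged
        rng = np.random.default_rng(7)
        d_ref = rng.choice([-1, 1], 40)
        d_tg = rng.choice([-1, 1], 40)
        markers, tg = self._tables(d_ref, d_tg)
        base = shift_consistency(markers, tg).concordance_fraction
        markers2, tg2 = self._tables(-d_ref, -d_tg)
        assert shift_consistency(markers2, tg2).concordance_fraction == base


class TestEndToEndRecovery:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_concordance_recovered(self, seed):
        data = simulate_shift_pair(
            ShiftSimParams(n_common_genes=800, n_null_genes=300,
                           n_cells_per_population=300, seed=seed)
        )
        model = DevelopmentalShiftModel(
            data.sc_counts, data.cell_labels, data.bulk_counts,
            data.tg_columns, data.control_columns,
        )
        res = model.fit(n_cells=300, seed=seed)
        assert res.concordance_fraction == pytest.approx(0.8, abs=0.05)
        rep = res.report.to_dict()
        assert rep["n_common"] <= min(rep["n_deg_bl_dev"], rep["n_deg_tg"])
        assert "concordance fraction" in res.summary()
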