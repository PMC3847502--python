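"""Differential expression and the transcript-group partition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import lignotx as lx
from lignotx.expression import GROUPS
from tests.conftest import SIX_SAMPLES, matrix_from_dict


def de_frame(gene_rows: dict[str, tuple[float, float, float]]) -> pd.DataFrame:
    """Hand-built DE result: gene -> (log2_fc, p, mean_a)."""
    return pd.DataFrame(
        {
            "log2_fc": {g: v[0] for g, v in gene_rows.items()},
            "p_value": {g: v[1] for g, v in gene_rows.items()},
            "mean_a": {g: v[2] for g, v in gene_rows.items()},
            "mean_b": {g: v[2] - v[0] for g, v in gene_rows.items()},
        }
    )


class TestReadExpression:
    def test_toy_tsv_parsed_with_layout(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text(
            "gene_id\tglucose.1\tglucose.2\tlactose.1\tlactose.2\tws.1\tws.2\n"
            "g1\t1\t2\t3\t4\t5\t6\ng2\t0\t0\t0\t0\t0\t0\n"
        )
        m = lx.read_expression(p)
        assert m.gene_ids == ["g1", "g2"]
        assert m.conditions == ["glucose", "lactose", "ws"]
        assert m.n_replicates("glucose") == 2

    def test_raw_zero_maps_to_log2_one(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene_id\tglc.1\tglc.2\ng1\t0\t1\n")
        m = lx.read_expression(p, raw=True)
        assert m.values.iloc[0, 0] == 0.0
        assert m.values.iloc[0, 1] == 1.0

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene_id\tglc.1\tglc.2\ng1\t1\toops\n")
        with pytest.raises(ValueError, match="g1.*glc.2"):
            lx.read_expression(p)

    def test_duplicate_gene_rejected(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene_id\tglc.1\tglc.2\ng1\t1\t2\ng1\t3\t4\n")
        with pytest.raises(ValueError, match="duplicate"):
            lx.read_expression(p)


class TestDifferentialExpression:
    def test_identical_replicates_give_null_result(self):
        m = matrix_from_dict({"g1": [5.0, 6.0, 5.0, 6.0]},
                             [("a", 1), ("a", 2), ("b", 1), ("b", 2)])
        de = lx.differential_expression(m, "a", "b")
        assert de.at["g1", "log2_fc"] == 0.0
        assert de.at["g1", "p_value"] == 1.0

    def test_two_log2_units_is_fourfold(self):
        m = matrix_from_dict(
            {"g1": [8.0, 8.0 + 1e-6, 6.0, 6.0 - 1e-6]},
            [("a", 1), ("a", 2), ("b", 1), ("b", 2)],
        )
        de = lx.differential_expression(m, "a", "b")
        assert de.at["g1", "log2_fc"] == pytest.approx(2.0, abs=1e-5)
        assert 2 ** de.at["g1", "log2_fc"] == pytest.approx(4.0, rel=1e-5)

    def test_student_matches_scipy_pooled_t(self):
        a, b = [7.1, 7.3, 7.2], [6.0, 6.2, 6.1]
        m = matrix_from_dict({"g1": a + b},
                             [("a", 1), ("a", 2), ("a", 3), ("b", 1), ("b", 2), ("b", 3)])
        de = lx.differential_expression(m, "a", "b")
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
        assert de.at["g1", "p_value"] == pytest.approx(p_ref, rel=1e-12)
        assert de.at["g1", "log2_fc"] == pytest.approx(np.mean(a) - np.mean(b))

    def test_welch_matches_scipy(self, rng):
        vals = rng.normal(6, 1, size=(30, 6))
        cols = [("a", 1), ("a", 2), ("a", 3), ("b", 1), ("b", 2), ("b", 3)]
        m = matrix_from_dict({f"g{i}": list(vals[i]) for i in range(30)}, cols)
        de = lx.differential_expression(m, "a", "b", method="welch")
        for i in range(30):
            _, p_ref = stats.ttest_ind(vals[i, :3], vals[i, 3:], equal_var=False)
            assert de.at[f"g{i}", "p_value"] == pytest.approx(p_ref, rel=1e-10)

    def test_single_replicate_errors(self):
        m = matrix_from_dict({"g1": [5.0, 6.0, 6.0]}, [("a", 1), ("b", 1), ("b", 2)])
        with pytest.raises(ValueError, match="replicates"):
            lx.differential_expression(m, "a", "b")


class TestClassification:
    def test_up_on_wheat_straw_only_is_group_a(self):
        ws = de_frame({"g": (2.0, 0.01, 8.0)})
        lac = de_frame({"g": (0.26, 0.3, 6.3)})
        wl = de_frame({"g": (1.74, 0.01, 8.0)})
        asn = lx.classify_transcript_groups(ws, lac, wl)
        assert asn.at["g", "group"] == "A"

    def test_equal_upregulation_on_both_is_group_e(self):
        ws = de_frame({"g": (2.0, 0.01, 8.0)})
        lac = de_frame({"g": (2.0, 0.01, 8.0)})
        wl = de_frame({"g": (0.0, 1.0, 8.0)})
        asn = lx.classify_transcript_groups(ws, lac, wl)
        assert asn.at["g", "group"] == "E"

    def test_direct_contrast_splits_c_and_d(self):
        ws = de_frame({"c": (3.0, 0.001, 9.0), "d": (1.5, 0.001, 7.5)})
        lac = de_frame({"c": (1.5, 0.001, 7.5), "d": (3.0, 0.001, 9.0)})
        wl = de_frame({"c": (1.5, 0.001, 9.0), "d": (-1.5, 0.001, 7.5)})
        asn = lx.classify_transcript_groups(ws, lac, wl)
        assert asn.at["c", "group"] == "C"
        assert asn.at["d", "group"] == "D"

    def test_universe_mismatch_reports_symmetric_difference(self):
        ws = de_frame({"g1": (0, 1, 6)})
        lac = de_frame({"g2": (0, 1, 6)})
        with pytest.raises(ValueError, match="g1.*g2|g2.*g1"):
            lx.classify_transcript_groups(ws, lac, ws)

    def test_partition_and_consistency_invariants(self, default_design):
        m, _ = lx.generate_expression(default_design)
        asn = lx.classify(m)
        assert set(asn["group"]) <= set(GROUPS)
        assert asn["group"].notna().all() and len(asn) == default_design.n_genes
        both = (asn["group"].isin(["C", "D", "E"])).sum()
        up_both = (asn["up_ws"] & asn["up_lac"] & (asn["group"] != "CONSTITUTIVE")).sum()
        assert both == up_both

    def test_tightening_thresholds_never_grows_the_induced_set(self, default_design):
        m, _ = lx.generate_expression(default_design)
        loose = lx.classify(m, lx.Thresholds(fold_change_min=2.0, p_max=0.05))
        tight_fc = lx.classify(m, lx.Thresholds(fold_change_min=3.0, p_max=0.05))
        tight_p = lx.classify(m, lx.Thresholds(fold_change_min=2.0, p_max=0.01))
        def n_induced(a):
            return a["group"].isin(["A", "B", "C", "D", "E"]).sum()
        assert n_induced(tight_fc) <= n_induced(loose)
        assert n_induced(tight_p) <= n_induced(loose)

    def test_order_invariance_under_row_and_column_permutation(self, default_design, rng):
        m, _ = lx.generate_expression(default_design)
        asn = lx.classify(m)
        perm_rows = rng.permutation(len(m.values))
        perm_cols = rng.permutation(m.values.shape[1])
        shuffled = lx.ExpressionMatrix(m.values.iloc[perm_rows, perm_cols])
        asn2 = lx.classify(shuffled)
        pd.testing.assert_series_equal(
            asn["group"].sort_index(), asn2["group"].sort_index()
        )

    def test_noiseless_recovery_is_perfect(self):
        d = lx.SyntheticDesign(n_genes=300, replicates_per_condition=3, noise_sd=0.0, seed=21)
        m, truth = lx.generate_expression(d)
        asn = lx.classify(m)
        expected = pd.Series(truth.groups).reindex(asn.index)
        assert (asn["group"] == expected).all()


class TestFindConstitutive:
    def _matrix(self, means):
        data = {"g": [means[0]] * 2 + [means[1]] * 2 + [means[2]] * 2}
        return matrix_from_dict(data, SIX_SAMPLES)

    def test_flat_gene_is_constitutive(self):
        assert lx.find_constitutive(self._matrix((6.0, 6.0, 6.0))) == ["g"]

    def test_ratio_above_band_excluded(self):
        m = self._matrix((6.0, 6.0, 6.0 + np.log2(1.5)))
        assert lx.find_constitutive(m) == []

    def test_band_edge_inclusive(self):
        m = self._matrix((6.0, 6.0 + np.log2(1.4), 6.0))
        assert lx.find_constitutive(m) == ["g"]

    def test_below_floor_excluded(self):
        m = self._matrix((0.5, 0.5, 0.5))
        assert lx.find_constitutive(m) == []


class TestCrosstab:
    def test_empty_annotation_counts_all_as_unannotated(self, default_design):
        m, _ = lx.generate_expression(default_design)
        asn = lx.classify(m)
        empty = lx.GeneAnnotation(pd.DataFrame(index=pd.Index([], name="gene_id")))
        tab = lx.crosstab_groups(asn, empty, facet="funcat")
        induced = asn["group"].isin(["A", "B", "C", "D", "E"])
        assert tab.loc["unannotated"].sum() == induced.sum()
        assert (tab.loc["All genes"] == tab.loc["unannotated"]).all()

    def test_direct_count_example(self):
        asn = pd.DataFrame({"group": ["A", "A", "A", "A", "B", "NONE"]},
                           index=[f"g{i}" for i in range(6)])
        ann = lx.GeneAnnotation(
            pd.DataFrame(
                {
                    "cazy_families": [["GH7"], ["CE5"], [], [], [], []],
                    "secreted": [True, True, False, False, False, False],
                },
                index=pd.Index([f"g{i}" for i in range(6)], name="gene_id"),
            )
        )
        tab = lx.crosstab_groups(asn, ann, facet="cazy_family")
        assert tab.at["GH7", "A"] == 1 and tab.at["CE5", "A"] == 1
        assert tab.at["All genes", "A"] == 4 and tab.at["All genes", "B"] == 1

    def test_counts_match_brute_force_tally(self, default_design):
        m, truth = lx.generate_expression(default_design)
        ann = lx.generate_annotation(default_design, truth)
        asn = lx.classify(m)
        tab = lx.crosstab_groups(asn, ann, facet="funcat")
        # independent tally over the truth tables
        for code in default_design.category_vocab:
            for grp in "ABCDE":
                expected = sum(
                    1
                    for g in asn.index[asn["group"] == grp]
                    if code in truth.categories.get(g, [])
                )
                got = tab.at[code, grp] if code in tab.index else 0
                assert got == expected

    def test_unknown_facet_rejected(self, default_design):
        m, truth = lx.generate_expression(default_design)
        ann = lx.generate_annotation(default_design, truth)
        with pytest.raises(ValueError, match="facet"):
            lx.crosstab_groups(lx.classify(m), ann, facet="bogus")


class TestPanelReport:
    def test_equal_means_ratio_one(self):
        m = matrix_from_dict({"g": [6.0, 6.0, 6.0, 6.0, 6.0, 6.0]}, SIX_SAMPLES)
        rep = lx.panel_report(m, ["g"])
        assert np.allclose(rep.table["ratio"], 1.0)

    def test_two_log2_units_is_ratio_four(self):
        m = matrix_from_dict({"g": [6.0, 6.0, 6.0, 6.0, 8.0, 8.0]}, SIX_SAMPLES)
        rep = lx.panel_report(m, ["g"])
        row = rep.table.set_index("condition").loc["wheat_straw"]
        assert row["ratio"] == pytest.approx(4.0)

    def test_planted_autophagy_panel_flagged_only_on_wheat_straw(self):
        d = lx.SyntheticDesign(
            n_genes=50, replicates_per_condition=3, seed=31,
            group_proportions={"A": 0.14, "NONE": 0.86},
        )
        m, truth = lx.generate_expression(d)
        panel = [g for g, grp in truth.groups.items() if grp == "A"][:7]
        rep = lx.panel_report(m, panel)
        t = rep.table.set_index(["gene_id", "condition"])
        for g in panel:
            assert bool(t.at[(g, "wheat_straw"), "significant_up"])
            assert not bool(t.at[(g, "lactose"), "significant_up"])

    def test_missing_gene_warns_not_fatal(self, toy_matrix):
        with pytest.warns(UserWarning, match="ghost"):
            rep = lx.panel_report(toy_matrix, ["gA", "ghost"])
        assert rep.missing == ["ghost"]
        assert set(rep.table["gene_id"]) == {"gA"}


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_group_counts_always_partition_universe(seed):
    d = lx.SyntheticDesign(n_genes=120, seed=seed)
    m, _ = lx.generate_expression(d)
    sizes = lx.group_sizes(lx.classify(m))
    assert sum(sizes.values()) == 120
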