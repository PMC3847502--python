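"""The generator plants recoverable truth and is deterministic per seed."""

import numpy as np
import pandas as pd
import pytest

import lignotx as lx
from lignotx.synthetic import assign_groups


class TestGenerateExpression:
    def test_degenerate_constitutive_no_noise_gives_flat_genes(self):
        d = lx.SyntheticDesign(
            n_genes=20,
            group_proportions={"CONSTITUTIVE": 1.0},
            noise_sd=0.0,
            within_band_jitter=0.0,
            seed=1,
        )
        m, truth = lx.generate_expression(d)
        vals = m.values.to_numpy()
        assert np.all(vals == vals[:, :1])
        assert set(truth.groups.values()) == {"CONSTITUTIVE"}

    def test_group_a_means_forced_by_construction(self):
        d = lx.SyntheticDesign(
            n_genes=10, group_proportions={"A": 1.0}, effect_size=2.0, noise_sd=0.0, seed=1
        )
        m, _ = lx.generate_expression(d)
        means = m.condition_means()
        assert np.allclose(means["wheat_straw"] - means["glucose"], 2.0)
        assert np.allclose(means["lactose"], means["glucose"])

    def test_bad_proportions_rejected_naming_field(self):
        with pytest.raises(ValueError, match="group_proportions"):
            lx.SyntheticDesign(group_proportions={"A": 0.5, "B": 0.4})

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            lx.SyntheticDesign(replicates_per_condition=1)

    def test_ground_truth_covers_every_gene_once(self, default_design):
        labels = assign_groups(default_design)
        assert sorted(labels) == default_design.gene_ids()
        sizes = pd.Series(labels).value_counts()
        assert sizes.sum() == default_design.n_genes

    def test_same_seed_identical_different_seed_same_structure(self, default_design):
        m1, t1 = lx.generate_expression(default_design)
        m2, t2 = lx.generate_expression(default_design)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        d3 = lx.SyntheticDesign(**{**default_design.__dict__, "seed": 99})
        m3, t3 = lx.generate_expression(d3)
        assert t1.groups == t3.groups  # structure shared
        assert not np.allclose(m1.values, m3.values)  # noise differs

    def test_expression_tsv_round_trip(self, tmp_path, default_design):
        m, _ = lx.generate_expression(default_design)
        path = tmp_path / "expr.tsv"
        m.to_tsv(path)
        back = lx.read_expression(path)
        pd.testing.assert_frame_equal(
            m.values, back.values, check_names=False, check_column_type=False
        )


class TestGenerateAnnotation:
    def test_null_annotation_frequencies_match_base_rate(self):
        d = lx.SyntheticDesign(
            n_genes=20000, seed=2, enriched_pairs=(), category_vocab=("c1", "c2"),
            category_base_rate=0.02,
        )
        truth = lx.GroundTruth(groups=assign_groups(d))
        ann = lx.generate_annotation(d, truth)
        for grp in ("A", "NONE"):
            genes = [g for g, lab in truth.groups.items() if lab == grp]
            rate = ann.in_category("c1").loc[genes].mean()
            assert rate == pytest.approx(0.02, abs=0.01)

    def test_odds_multiplier_hits_expected_membership_rate(self):
        # odds 0.02/0.98 * 10 -> probability 0.2041/1.2041 = 0.169
        d = lx.SyntheticDesign(
            n_genes=100_000, seed=3, group_proportions={"A": 1.0},
            category_vocab=("cat",), category_base_rate=0.02,
            enriched_pairs=(("A", "cat", 10.0),),
        )
        truth = lx.GroundTruth(groups=assign_groups(d))
        ann = lx.generate_annotation(d, truth)
        assert ann.in_category("cat").mean() == pytest.approx(0.169, abs=0.005)

    def test_unknown_category_code_rejected(self):
        d = lx.SyntheticDesign(enriched_pairs=(("A", "no.such.code", 2.0),))
        truth = lx.GroundTruth(groups=assign_groups(d))
        with pytest.raises(ValueError, match="no.such.code"):
            lx.generate_annotation(d, truth)

    def test_annotation_tsv_byte_identical_on_rerun(self, tmp_path, default_design):
        truth = lx.GroundTruth(groups=assign_groups(default_design))
        p1, p2 = tmp_path / "a1.tsv", tmp_path / "a2.tsv"
        lx.generate_annotation(default_design, truth).to_tsv(p1)
        lx.generate_annotation(default_design, truth).to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_annotation_round_trip(self, tmp_path, default_design):
        truth = lx.GroundTruth(groups=assign_groups(default_design))
        ann = lx.generate_annotation(default_design, truth)
        path = tmp_path / "ann.tsv"
        ann.to_tsv(path)
        back = lx.GeneAnnotation.from_tsv(path)
        pd.testing.assert_frame_equal(ann.table, back.table, check_names=False)


class TestGeneratePromoters:
    def test_zero_planted_sites_scan_zero(self):
        d = lx.SyntheticDesign(seed=4, planted_sites_per_promoter={"g1": 0, "g2": 0})
        proms, truth = lx.generate_promoters(d)
        assert all(r.count == 0 for r in lx.scan_promoters(proms))
        assert truth.motif_counts == {"g1": 0, "g2": 0}

    def test_six_planted_sites_scanned_as_six(self):
        d = lx.SyntheticDesign(seed=5, planted_sites_per_promoter={"man1": 6})
        proms, _ = lx.generate_promoters(d)
        (res,) = lx.scan_promoters(proms)
        assert res.count == 6

    def test_average_sites_per_gene_is_planted_mean(self):
        d = lx.SyntheticDesign(seed=6, planted_sites_per_promoter={"g1": 3, "g2": 1})
        proms, _ = lx.generate_promoters(d)
        assert lx.average_sites_per_gene(lx.scan_promoters(proms)) == 2.0

    def test_overfull_promoter_rejected_naming_gene(self):
        d = lx.SyntheticDesign(
            seed=7, promoter_length=20, planted_sites_per_promoter={"crowded": 5}
        )
        with pytest.raises(ValueError, match="crowded"):
            lx.generate_promoters(d)

    def test_scan_recovers_planted_positions(self):
        d = lx.SyntheticDesign(seed=8, planted_sites_per_promoter={"g1": 4})
        proms, truth = lx.generate_promoters(d)
        (res,) = lx.scan_promoters(proms)
        assert res.positions == truth.motif_positions["g1"]

    def test_fasta_round_trip(self, tmp_path):
        d = lx.SyntheticDesign(seed=9, planted_sites_per_promoter={"g1": 2, "g2": 0})
        proms, _ = lx.generate_promoters(d)
        path = tmp_path / "prom.fasta"
        proms.to_fasta(path)
        back = lx.PromoterSet.from_fasta(path)
        assert back.sequences == proms.sequences


class TestGenerateQpcr:
    def test_unit_ratios_no_noise_recovered_exactly(self):
        d = lx.SyntheticDesign(seed=10, ct_noise_sd=0.0, qpcr_true_ratios={"x": 1.0, "y": 1.0})
        exp, _ = lx.generate_qpcr(d)
        for g in ("x", "y"):
            assert lx.pfaffl_ratio(exp, g, "ws_24h").ratio == pytest.approx(1.0)

    def test_fourfold_ratio_means_two_cycles_at_e2(self):
        d = lx.SyntheticDesign(seed=11, ct_noise_sd=0.0, qpcr_true_ratios={"x": 4.0})
        exp, _ = lx.generate_qpcr(d)
        dct_gene = exp.cts("x", "glc_8h").mean() - exp.cts("x", "ws_24h").mean()
        dct_norm = exp.cts("tef1", "glc_8h").mean() - exp.cts("tef1", "ws_24h").mean()
        assert dct_gene - dct_norm == pytest.approx(2.0, abs=1e-12)

    def test_pfaffl_round_trip_with_nonideal_efficiency(self):
        d = lx.SyntheticDesign(
            seed=12, ct_noise_sd=0.0, efficiencies={"x": 1.9}, qpcr_true_ratios={"x": 0.5}
        )
        exp, truth = lx.generate_qpcr(d)
        assert lx.pfaffl_ratio(exp, "x", "ws_24h").ratio == pytest.approx(0.5, abs=1e-12)
        assert truth.qpcr_ratios == {"x": 0.5}

    def test_missing_normalizer_efficiency_bounds_checked(self):
        with pytest.raises(ValueError, match="normalizer"):
            d = lx.SyntheticDesign(seed=13, qpcr_true_ratios={"tef1": 2.0})
            lx.generate_qpcr(d)

    def test_qpcr_tsv_round_trip(self, tmp_path):
        d = lx.SyntheticDesign(seed=14, qpcr_true_ratios={"x": 3.0})
        exp, _ = lx.generate_qpcr(d)
        path = tmp_path / "qpcr.tsv"
        exp.to_tsv(path)
        back = lx.QpcrExperiment.from_tsv(path)
        assert np.allclose(back.cts("x", "ws_24h"), exp.cts("x", "ws_24h"))
        assert back.efficiencies == exp.efficiencies


class TestGroundTruthIO:
    def test_truth_json_round_trip(self, tmp_path, default_design):
        _, truth = lx.generate_expression(default_design)
        lx.generate_annotation(default_design, truth)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = lx.GroundTruth.from_json(path)
        assert back.groups == truth.groups
        assert back.categories == truth.categories
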