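import numpy as np
import pandas as pd
import pytest

from clonsel.synthetic_data import (CloneModel, SegmentPlan,
                                    default_ploidy_plan, default_config,
                                    expected_segment_label,
                                    fragment_lengths_from_config, load_config,
                                    simulate_expression, simulate_from_config,
                                    simulate_pair, simulate_read_pairs,
                                    write_pair)


class TestValidation:
    def test_fractions_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            CloneModel(ancestral_fraction=1.5)
        with pytest.raises(ValueError):
            CloneModel(resistant_subclone_fraction_resistant=-0.1)

    def test_negative_counts_and_bad_depth_rejected(self):
        with pytest.raises(ValueError):
            CloneModel(n_selected_variants=-1)
        with pytest.raises(ValueError):
            CloneModel(mean_depth=0)

    def test_segment_plan_configuration_checked(self):
        with pytest.raises(ValueError):
            SegmentPlan("chr1", 1, 100, k_sensitive=2, m_sensitive=2)
        with pytest.raises(ValueError):
            SegmentPlan("chr1", 100, 1)

    def test_seed_must_be_a_fixed_integer(self):
        with pytest.raises(ValueError, match="seed"):
            simulate_pair(seed=None)
        with pytest.raises(ValueError):
            simulate_expression(seed="random")

    def test_nonpositive_fold_change_rejected(self):
        plan = pd.DataFrame({"gene_index": [0], "fold_change": [-2.0]})
        with pytest.raises(ValueError, match="fold change"):
            simulate_expression(n_genes=10, de_plan=plan, seed=0)


class TestPlantedAars:
    def test_pure_ancestral_diploid_pair_has_aar_half(self):
        model = CloneModel(ancestral_fraction=1.0,
                           resistant_subclone_fraction_sensitive=0.0,
                           resistant_subclone_fraction_resistant=0.0,
                           n_ancestral_variants=100, n_selected_variants=0,
                           n_depleted_variants=0, n_neutral_variants=0)
        plan = [SegmentPlan("chr1", 1, 10_000_000, n_het_sites=0)]
        sim = simulate_pair(model, plan, seed=1)
        truth = sim.truth.variants
        assert (truth["true_aar_sensitive"] == 0.5).all()
        assert (truth["true_aar_resistant"] == 0.5).all()

    def test_subclone_variant_matches_de_novo_af_pattern(self):
        # fraction 0 before treatment, 0.7 after, het in a diploid
        # region: true AARs 0 -> 0.35
        model = CloneModel(n_ancestral_variants=0, n_selected_variants=10,
                           n_depleted_variants=0, n_neutral_variants=0)
        plan = [SegmentPlan("chr1", 1, 10_000_000, n_het_sites=0)]
        sim = simulate_pair(model, plan, seed=2)
        truth = sim.truth.variants
        assert (truth["true_aar_sensitive"] == 0.0).all()
        assert np.allclose(truth["true_aar_resistant"], 0.35)
        assert (truth["category"] == "selected_up").all()

    def test_truth_counts_match_the_requested_plan(self, small_pair):
        truth = small_pair.truth.variants
        by_source = truth.groupby("source").size()
        assert by_source["ancestral"] == 300
        assert by_source["error"] == 300
        assert by_source["subclone"] == 100  # 60 selected + 40 depleted
        sub = truth[truth["source"] == "subclone"]
        assert (sub["category"] == "selected_up").sum() == 60
        assert (sub["category"] == "selected_down").sum() == 40
        het = truth[truth["source"] == "germline_het"]
        assert len(het) == sum(s.n_het_sites for s in default_ploidy_plan())

    def test_each_variant_appears_exactly_once(self, small_pair):
        keys = ["chrom", "pos", "ref", "alt"]
        truth = small_pair.truth.variants
        assert not truth.duplicated(keys).any()
        assert len(truth) == len(small_pair.counts_sensitive) \
            == len(small_pair.counts_resistant) == len(small_pair.annotations)

    def test_categories_are_consistent_with_planted_aars(self, small_pair):
        truth = small_pair.truth.variants
        delta = truth["true_aar_resistant"] - truth["true_aar_sensitive"]
        assert (delta[truth["category"] == "selected_up"] >= 0.1).all()
        assert (delta[truth["category"] == "selected_down"] <= -0.1).all()
        anc = truth["category"] == "ancestral"
        assert (delta[anc].abs() < 0.1).all()

    def test_empirical_mean_aar_converges_to_planted_value(self):
        model = CloneModel(n_ancestral_variants=3000, n_selected_variants=0,
                           n_depleted_variants=0, n_neutral_variants=0)
        plan = [SegmentPlan("chr1", 1, 50_000_000, n_het_sites=0)]
        sim = simulate_pair(model, plan, seed=3)
        counts = sim.counts_sensitive
        depth = counts["ref_count"] + counts["alt_count"]
        ok = depth > 0
        ratios = counts.loc[ok, "alt_count"] / depth[ok]
        se = np.sqrt((0.5 * 0.5 / depth[ok]).mean() / ok.sum())
        assert abs(ratios.mean() - 0.5) <= 3 * se


class TestDeterminism:
    def test_same_seed_byte_identical_pair(self):
        a = simulate_pair(seed=5)
        b = simulate_pair(seed=5)
        for left, right in ((a.counts_sensitive, b.counts_sensitive),
                            (a.counts_resistant, b.counts_resistant),
                            (a.annotations, b.annotations),
                            (a.truth.variants, b.truth.variants)):
            assert left.to_csv(index=False) == right.to_csv(index=False)

    def test_different_seeds_differ(self):
        a = simulate_pair(seed=5)
        b = simulate_pair(seed=6)
        assert a.counts_sensitive.to_csv() != b.counts_sensitive.to_csv()

    def test_expression_and_reads_are_seed_repeatable(self):
        c1, t1 = simulate_expression(n_genes=300, seed=9)
        c2, t2 = simulate_expression(n_genes=300, seed=9)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(t1, t2)
        p1, _ = simulate_read_pairs([150, 180], seed=9)
        p2, _ = simulate_read_pairs([150, 180], seed=9)
        assert p1 == p2


class TestExpressionTruth:
    def test_unit_fold_changes_give_unit_expected_ratio(self):
        plan = pd.DataFrame({"gene_index": [], "fold_change": []})
        counts, truth = simulate_expression(n_genes=4000, de_plan=plan,
                                            seed=13)
        assert (truth["fold_change"] == 1.0).all()
        ratio = counts["count_resistant"].sum() / counts["count_sensitive"].sum()
        assert ratio == pytest.approx(1.0, rel=0.02)

    def test_seventeen_fold_down_gene_is_marked_de_down(self):
        counts, truth = simulate_expression(n_genes=500, seed=13)
        strong = truth[np.isclose(truth["fold_change"], 1 / 17)]
        assert len(strong) == 1
        assert strong.iloc[0]["is_de_true"] and strong.iloc[0]["direction"] == "down"

    def test_library_size_factors_scale_counts(self):
        plan = pd.DataFrame({"gene_index": [], "fold_change": []})
        counts, _ = simulate_expression(n_genes=4000, de_plan=plan,
                                        library_sizes=(1.0, 2.0), seed=14)
        ratio = counts["count_resistant"].sum() / counts["count_sensitive"].sum()
        assert ratio == pytest.approx(2.0, rel=0.05)


class TestAnnotationsAndSegments:
    def test_segdup_fraction_of_noise_sites(self, small_pair):
        truth = small_pair.truth.variants
        keys = ["chrom", "pos", "ref", "alt"]
        ann = small_pair.annotations.merge(truth[keys + ["source"]], on=keys)
        noise = ann[ann["source"] == "error"]
        frac = noise["in_segdup"].mean()
        assert 0.04 < frac < 0.18  # nominal 10%
        assert not ann.loc[ann["source"] == "subclone", "in_segdup"].any()

    def test_selected_variants_are_cosmic_catalogued(self, small_pair):
        truth = small_pair.truth.variants
        keys = ["chrom", "pos", "ref", "alt"]
        ann = small_pair.annotations.merge(truth[keys + ["source"]], on=keys)
        sub = ann[ann["source"] == "subclone"]
        assert sub["in_cosmic"].all()
        assert (sub["location_class"] == "exonic").all()
        assert "TP53" in set(sub["gene"])

    def test_expected_segment_labels_are_lowest_terms(self):
        assert expected_segment_label(2, 1) == "-"
        assert expected_segment_label(4, 2) == "-"
        assert expected_segment_label(4, 3) == "tetra-ploidy"
        assert expected_segment_label(6, 4) == "tri-ploidy"


class TestConfigAndOutput:
    def test_config_round_trip_drives_the_generator(self, tmp_path):
        cfg = default_config()
        cfg["clone_model"] = {"n_ancestral_variants": 50,
                              "n_selected_variants": 5,
                              "n_depleted_variants": 5,
                              "n_neutral_variants": 50}
        path = tmp_path / "config.yaml"
        import yaml
        path.write_text(yaml.safe_dump(cfg))
        sim = simulate_from_config(load_config(path), seed=17)
        assert len(sim.truth.variants) == 110 + sum(
            s["n_het_sites"] for s in cfg["ploidy_plan"])
        frags = fragment_lengths_from_config(cfg, seed=17)
        assert len(frags) == cfg["reads"]["n_pairs"]
        assert (frags >= cfg["reads"]["read_length"]).all()

    def test_write_pair_produces_all_text_outputs(self, small_pair, tmp_path):
        paths = write_pair(small_pair, tmp_path / "out")
        for name, path in paths.items():
            assert (tmp_path / "out").joinpath(path.split("/")[-1]).exists(), name
        bed_first = (tmp_path / "out" / "region_grid.bed").read_text() \
            .splitlines()[0].split("\t")
        assert bed_first[1] == "0"  # 0-based half-open on disk
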