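import itertools

import numpy as np
import pandas as pd
import pytest

from clonsel.selection_filter import (RULES, AnnotationRecord, apply_filter,
                                      filter_summary, load_annotations,
                                      passes_inclusion, write_annotations)
from clonsel.variants import Thresholds


def _ann(**kwargs) -> AnnotationRecord:
    base = dict(chrom="chr1", pos=100, ref="A", alt="T", gene="GENE",
                location_class="exonic", exonic_class="nonsynonymous")
    base.update(kwargs)
    return AnnotationRecord(**base)


def _rec(ref_s=140, alt_s=10, ref_r=100, alt_r=50):
    return {"ref_s": ref_s, "alt_s": alt_s, "ref_r": ref_r, "alt_r": alt_r}


class TestDecisionTree:
    def test_cosmic_branch_admits_hotspot_like_variant(self):
        # catalogued somatic variant, no population frequency, deep coverage
        include, trace = passes_inclusion(
            _rec(150, 0, 119, 21), _ann(gene="NRAS", in_cosmic=True))
        assert include
        assert dict(trace)["evidence"] == "cosmic"

    def test_synonymous_variant_fails_the_coding_rule(self):
        include, trace = passes_inclusion(
            _rec(), _ann(exonic_class="synonymous", in_cosmic=True))
        assert not include
        assert dict(trace)["coding"] == "fail"

    def test_segmental_duplication_is_never_reported(self):
        include, trace = passes_inclusion(
            _rec(), _ann(in_cosmic=True, in_segdup=True))
        assert not include
        assert dict(trace)["segdup"] == "fail"

    def test_novel_variant_needs_one_deleterious_prediction(self):
        tolerated = _ann(sift="tolerated", polyphen_hdiv="benign")
        assert not passes_inclusion(_rec(), tolerated)[0]
        either = _ann(sift="deleterious", polyphen_hdiv="benign")
        assert passes_inclusion(_rec(), either)[0]

    def test_dbsnp_variant_needs_both_deleterious_predictions(self):
        one_of_two = _ann(dbsnp_id="rs123", sift="deleterious",
                          polyphen_hdiv="benign")
        assert not passes_inclusion(_rec(), one_of_two)[0]
        both = _ann(dbsnp_id="rs123", sift="deleterious",
                    polyphen_hdiv="deleterious")
        assert passes_inclusion(_rec(), both)[0]

    def test_common_population_variant_without_cosmic_is_excluded(self):
        # a 1000g CEU variant has no admitting branch unless in COSMIC
        assert not passes_inclusion(_rec(), _ann(ceu_af=0.01))[0]
        assert passes_inclusion(_rec(), _ann(ceu_af=0.01, in_cosmic=True))[0]
        # and a frequent one is excluded even when catalogued
        assert not passes_inclusion(_rec(), _ann(ceu_af=0.2, in_cosmic=True))[0]

    def test_possibly_damaging_is_not_deleterious(self):
        ann = _ann(sift="tolerated", polyphen_hdiv="possibly_damaging")
        assert not passes_inclusion(_rec(), ann)[0]

    def test_depth_rule_is_strict_and_applies_to_both_samples(self):
        ann = _ann(in_cosmic=True)
        assert not passes_inclusion(_rec(ref_s=5, alt_s=5), ann)[0]   # == 10
        assert passes_inclusion(_rec(ref_s=5, alt_s=6), ann)[0]       # == 11
        missing = _rec()
        missing["ref_s"] = float("nan")
        missing["alt_s"] = float("nan")
        include, trace = passes_inclusion(missing, ann)
        assert not include and dict(trace)["depth"] == "fail"

    def test_genotype_rule_requires_non_hom_ref_in_at_least_one_sample(self):
        ann = _ann(in_cosmic=True)
        # de-novo appearance: hom-ref sensitive, variant resistant -> kept
        assert passes_inclusion(_rec(100, 0, 65, 35), ann)[0]
        # hom-ref in both -> excluded
        include, trace = passes_inclusion(_rec(100, 1, 100, 1), ann)
        assert not include and dict(trace)["genotype"] == "fail"

    def test_unannotated_record_is_excluded_and_flagged(self):
        include, trace = passes_inclusion(_rec(), None)
        assert not include
        assert trace == [("annotation", "unannotated")]

    def test_trace_covers_every_rule_in_fixed_order(self):
        _, trace = passes_inclusion(_rec(), _ann(in_cosmic=True))
        assert [r for r, _ in trace] == list(RULES)


def test_decision_matches_brute_force_truth_table():
    """Exhaustive check of the decision tree against a direct boolean
    re-expression of the published rules."""
    thr = Thresholds()
    count_cases = [(150, 0, 119, 21), (5, 5, 100, 50), (100, 1, 100, 1)]
    grid = itertools.product(
        count_cases,
        ["exonic", "splicing", "intronic"],           # location
        ["nonsynonymous", "synonymous"],              # exonic class
        [False, True],                                # in_cosmic
        [None, "rs1"],                                # dbsnp
        [None, 0.01, 0.2],                            # ceu_af
        [None, "deleterious", "tolerated"],           # sift
        [None, "deleterious", "benign"],              # polyphen
        [False, True],                                # segdup
    )
    from clonsel.variants import NON_HOM_REF, estimate_genotype
    n_checked = 0
    for counts, loc, exo, cosmic, dbsnp, ceu, sift, poly, segdup in grid:
        rec = _rec(*counts)
        ann = _ann(location_class=loc, exonic_class=exo, in_cosmic=cosmic,
                   dbsnp_id=dbsnp, ceu_af=ceu, sift=sift,
                   polyphen_hdiv=poly, in_segdup=segdup)
        include, _ = passes_inclusion(rec, ann, thr)

        gt = NON_HOM_REF in (estimate_genotype(rec["ref_s"], rec["alt_s"], thr),
                             estimate_genotype(rec["ref_r"], rec["alt_r"], thr))
        depth = (rec["ref_s"] + rec["alt_s"] > 10) and \
                (rec["ref_r"] + rec["alt_r"] > 10)
        coding = loc == "exonic" and exo != "synonymous"
        branch_a = cosmic and (ceu is None or ceu < 0.05)
        branch_b = ceu is None and dbsnp is None and \
            ("deleterious" in (sift, poly))
        branch_c = ceu is None and dbsnp is not None and \
            sift == "deleterious" and poly == "deleterious"
        expected = gt and depth and coding and not segdup and \
            (branch_a or branch_b or branch_c)
        assert include == expected, (counts, loc, exo, cosmic, dbsnp, ceu,
                                     sift, poly, segdup)
        n_checked += 1
    assert n_checked == 3 * 3 * 2 * 2 * 2 * 3 * 3 * 3 * 2


def test_adding_cosmic_evidence_never_revokes_inclusion():
    """Monotonicity: flipping in_cosmic on (with ceu absent) can only
    keep or gain inclusion."""
    rng = np.random.default_rng(4)
    for _ in range(200):
        ann = _ann(
            location_class=str(rng.choice(["exonic", "intronic"])),
            exonic_class=str(rng.choice(["nonsynonymous", "synonymous"])),
            in_cosmic=False,
            dbsnp_id=None if rng.random() < 0.5 else "rs1",
            ceu_af=None,
            sift=[None, "deleterious", "tolerated"][rng.integers(3)],
            polyphen_hdiv=[None, "deleterious", "benign"][rng.integers(3)],
            in_segdup=bool(rng.random() < 0.3))
        rec = _rec()
        before, _ = passes_inclusion(rec, ann)
        after, _ = passes_inclusion(
            rec, AnnotationRecord(**{**ann.__dict__, "in_cosmic": True}))
        assert after >= before


class TestTableLevel:
    def test_apply_filter_audit_and_summary(self, small_pair, small_merged,
                                            thresholds):
        filtered = apply_filter(small_merged, small_pair.annotations, thresholds)
        summary = filter_summary(filtered)
        assert summary["total"] == len(small_merged)
        conserved = summary["included"] + summary["unannotated"] + \
            sum(summary["excluded_by_rule"].values())
        assert conserved == summary["total"]
        # audit columns carry a verdict for every rule
        for rule in RULES:
            assert filtered[f"rule_{rule}"].ne("").all()
        # planted subclone variants are COSMIC-catalogued and pass
        truth = small_pair.truth.variants
        keys = ["chrom", "pos", "ref", "alt"]
        sub = truth[truth["source"] == "subclone"].merge(filtered, on=keys)
        deep = (sub["ref_s"] + sub["alt_s"] > 10) & \
               (sub["ref_r"] + sub["alt_r"] > 10)
        assert (sub.loc[deep, "include"]).mean() > 0.95

    def test_annotation_round_trip(self, small_pair, tmp_path):
        path = tmp_path / "ann.tsv"
        write_annotations(small_pair.annotations, path)
        back = load_annotations(path)
        pd.testing.assert_frame_equal(
            back, small_pair.annotations.reset_index(drop=True),
            check_dtype=False, atol=1e-12)

    def test_missing_annotations_counted_separately(self, small_merged,
                                                    small_pair, thresholds):
        partial = small_pair.annotations.iloc[:-20]
        filtered = apply_filter(small_merged, partial, thresholds)
        summary = filter_summary(filtered)
        assert summary["unannotated"] > 0
        assert (filtered.loc[filtered["reason"] == "unannotated",
                             "include"] == False).all()  # noqa: E712


def test_annotation_record_validation():
    with pytest.raises(ValueError):
        _ann(location_class="weird")
    with pytest.raises(ValueError):
        _ann(ceu_af=1.5)
    with pytest.raises(ValueError):
        _ann(sift="damaging")
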