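import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirnome.isoforms import (
    arm_expression,
    arm_ratios,
    class_contribution_summary,
    classify_isomirs,
    classify_offsets,
    classify_suffix,
    isomir_count_distribution,
    isomir_shift_screen,
    isomir_table,
    nta_contribution_summary,
    nta_screens,
    nta_tables,
    present_isomirs,
)
from mirnome.reference_io import MultiLocusGroup
from mirnome.tag_io import Library

from conftest import make_assignment

G1 = MultiLocusGroup("miR-1-5p", ("mir-1",), "ACGTACGTACGTACGTACGTAC")
G2 = MultiLocusGroup("miR-2-5p", ("mir-2",), "TTGCATTGCATTGCATTGCATG")


class TestClassification:
    @pytest.mark.parametrize("o5,o3,expected", [
        (0, 0, "canonical"),
        (0, 2, "end_site_3p"),
        (0, -1, "end_site_3p"),
        (-1, 0, "start_site_5p"),
        (2, 0, "start_site_5p"),
        (1, -1, "both_sites"),
    ])
    def test_offset_classes(self, o5, o3, expected):
        assert classify_offsets(o5, o3) == expected

    @pytest.mark.parametrize("suffix,expected", [
        ("A", "adenylated"), ("AA", "adenylated"),
        ("T", "uridylated"), ("TTT", "uridylated"),
        ("C", "other_single"), ("GG", "other_single"),
        ("TA", "mixed"), ("AGT", "mixed"),
    ])
    def test_suffix_classes(self, suffix, expected):
        assert classify_suffix(suffix) == expected

    @settings(max_examples=100, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=6))
    def test_suffix_classification_exhaustive_and_exclusive(self, suffix):
        assert classify_suffix(suffix) in {"adenylated", "uridylated",
                                           "other_single", "mixed"}


class TestIsomirTable:
    def test_all_canonical_gives_single_key(self):
        by_sample = {"s1": [make_assignment(G1, 50), make_assignment(G1, 30)]}
        t = isomir_table(by_sample)
        assert len(t) == 1
        assert t.iloc[0][["offset5", "offset3", "count"]].tolist() == [0, 0, 80]

    def test_hand_tally_and_fractions(self):
        by_sample = {"s1": [
            make_assignment(G1, 93), make_assignment(G1, 5, offset3=1),
            make_assignment(G1, 1, offset3=-1), make_assignment(G1, 1, offset5=1),
        ]}
        t = isomir_table(by_sample)
        assert t["count"].sum() == 100
        assert t["fraction"].sum() == pytest.approx(1.0)
        present = present_isomirs(t, 0.01)
        # all four reach the 1 % floor (boundary inclusive)
        assert len(present["s1"]["miR-1-5p"]) == 4

    def test_presence_boundary_is_inclusive_at_one_percent(self):
        by_sample = {"s1": [
            make_assignment(G1, 991), make_assignment(G1, 9, offset3=1),  # 0.9 %
            make_assignment(G2, 990), make_assignment(G2, 10, offset3=1),  # 1.0 %
        ]}
        present = present_isomirs(isomir_table(by_sample), 0.01)
        assert present["s1"]["miR-1-5p"] == {(0, 0)}
        assert present["s1"]["miR-2-5p"] == {(0, 0), (0, 1)}

    def test_empty_input(self):
        t = isomir_table({"s1": []})
        assert t.empty
        assert present_isomirs(t) == {}


class TestDistribution:
    def test_identical_distributions_give_null_chi2(self):
        by_sample = {
            s: [make_assignment(G1, 60), make_assignment(G1, 40, offset3=1)]
            for s in ("s1", "s2", "s3", "s4")
        }
        tissue = {"s1": "normal", "s2": "normal", "s3": "tumor", "s4": "tumor"}
        hist, test = isomir_count_distribution(isomir_table(by_sample), tissue)
        assert hist.loc["normal"].equals(hist.loc["tumor"])
        if test is not None:  # single shared bin -> test skipped
            assert test[0] == pytest.approx(0.0)

    def test_single_tissue_skips_test(self):
        by_sample = {"s1": [make_assignment(G1, 200), make_assignment(G1, 100, offset3=1)]}
        _, test = isomir_count_distribution(isomir_table(by_sample), {"s1": "normal"})
        assert test is None

    def test_low_coverage_matures_excluded(self):
        by_sample = {"s1": [make_assignment(G1, 99), make_assignment(G2, 100)]}
        hist, _ = isomir_count_distribution(
            isomir_table(by_sample), {"s1": "normal"}, min_reads=100
        )
        assert hist.to_numpy().sum() == 1  # only miR-2-5p counted


class TestClassContributions:
    def test_mirbase_dominant_is_fixed_point_of_redefinition(self):
        by_sample = {"s1": [make_assignment(G1, 80), make_assignment(G1, 20, offset3=1)]}
        t = isomir_table(by_sample)
        a = classify_isomirs(t, "mirbase")
        b = classify_isomirs(t, "normal_dominant", {"s1": "normal"})
        pd.testing.assert_frame_equal(a, b)

    def test_dominant_redefinition_reindexes_offsets(self):
        # the (+1, 0) isoform dominates normals: it becomes 'canonical' and
        # the miRBase canonical re-classes as a 5' variant at (-1, 0)
        by_sample = {"s1": [make_assignment(G1, 30), make_assignment(G1, 70, offset5=1)]}
        t = isomir_table(by_sample)
        out = classify_isomirs(t, "normal_dominant", {"s1": "normal"})
        frac = dict(zip(out["class"], out["fraction"]))
        assert frac["canonical"] == pytest.approx(0.70)
        assert frac["start_site_5p"] == pytest.approx(0.30)

    def test_class_fractions_sum_to_one(self):
        by_sample = {"s1": [
            make_assignment(G1, 50), make_assignment(G1, 25, offset3=2),
            make_assignment(G1, 15, offset5=-1), make_assignment(G1, 10, offset5=1, offset3=1),
        ]}
        out = classify_isomirs(isomir_table(by_sample))
        frac = dict(zip(out["class"], out["fraction"]))
        assert frac == pytest.approx(
            {"canonical": 0.50, "end_site_3p": 0.25,
             "start_site_5p": 0.15, "both_sites": 0.10}
        )
        assert out["fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_summary_selects_matures_covered_in_every_sample(self):
        by_sample = {
            "s1": [make_assignment(G1, 150), make_assignment(G2, 150)],
            "s2": [make_assignment(G1, 150), make_assignment(G2, 50)],
        }
        t = isomir_table(by_sample)
        totals = t.groupby(["sample_id", "mature_id"])["count"].sum()
        summary = class_contribution_summary(classify_isomirs(t), totals, min_reads=100)
        assert list(summary.index) == ["miR-1-5p"]
        assert summary.loc["miR-1-5p", "dominant_class"] == "canonical"


class TestShiftScreen:
    TISSUE = {"n1": "normal", "n2": "normal", "t1": "tumor", "t2": "tumor"}

    def test_no_variation_yields_empty(self):
        by_sample = {s: [make_assignment(G1, 70), make_assignment(G1, 30, offset3=1)]
                     for s in self.TISSUE}
        hits = isomir_shift_screen(isomir_table(by_sample), self.TISSUE,
                                   [("tumor", "normal")])
        assert hits.empty

    def test_planted_shift_reported(self):
        by_sample = {
            "n1": [make_assignment(G1, 70), make_assignment(G1, 30, offset3=1)],
            "n2": [make_assignment(G1, 70), make_assignment(G1, 30, offset3=1)],
            "t1": [make_assignment(G1, 45), make_assignment(G1, 55, offset3=1)],
            "t2": [make_assignment(G1, 45), make_assignment(G1, 55, offset3=1)],
        }
        hits = isomir_shift_screen(isomir_table(by_sample), self.TISSUE,
                                   [("tumor", "normal")], threshold=0.20)
        keys = set(zip(hits["offset5"], hits["offset3"]))
        assert keys == {(0, 0), (0, 1)}  # the 25 % swap moves both isoforms
        assert hits["delta"].abs().tolist() == pytest.approx([0.25, 0.25])

    def test_threshold_zero_reports_everything(self):
        by_sample = {s: [make_assignment(G1, 70), make_assignment(G1, 30, offset3=1)]
                     for s in self.TISSUE}
        hits = isomir_shift_screen(isomir_table(by_sample), self.TISSUE,
                                   [("tumor", "normal")], threshold=0.0)
        assert len(hits) == 2


class TestNta:
    def test_no_suffixes_gives_zero_profile(self):
        profiles, suffixes = nta_tables({"s1": [make_assignment(G1, 10)]})
        assert profiles[["adenylated", "uridylated", "other_single", "mixed"]].sum().sum() == 0
        assert suffixes.empty

    def test_class_fractions_from_hand_mixture(self):
        by_sample = {"s1": [
            make_assignment(G1, 60),
            make_assignment(G1, 15, nta="A"), make_assignment(G1, 10, nta="AA"),
            make_assignment(G1, 10, nta="T"), make_assignment(G1, 5, nta="TA"),
        ]}
        profiles, _ = nta_tables(by_sample)
        row = profiles.iloc[0]
        assert row["adenylated"] == pytest.approx(0.25)
        assert row["uridylated"] == pytest.approx(0.10)
        assert row["mixed"] == pytest.approx(0.05)
        assert row["total_mapped"] == 100

    def test_global_summary_pools_rare_additions_into_other(self):
        by_sample = {"s1": [
            make_assignment(G1, 880), make_assignment(G1, 100, nta="A"),
            make_assignment(G1, 15, nta="T"), make_assignment(G1, 5, nta="GC"),
        ]}
        profiles, suffixes = nta_tables(by_sample)
        summary = nta_contribution_summary(suffixes, profiles, min_reads=100)
        assert summary["A"] == pytest.approx(0.10)
        assert summary["T"] == pytest.approx(0.015)
        assert summary["other"] == pytest.approx(0.005)

    def test_screen_flags_planted_tumor_adenylation(self):
        tissue = {"n1": "normal", "t1": "tumor"}
        by_sample = {
            "n1": [make_assignment(G1, 95), make_assignment(G1, 5, nta="A")],
            "t1": [make_assignment(G1, 60), make_assignment(G1, 40, nta="A")],
        }
        profiles, _ = nta_tables(by_sample)
        res = nta_screens(profiles, tissue, [("tumor", "normal")], delta=0.20, level=0.30)
        assert res["shift_hits"]["mature_id"].tolist() == ["miR-1-5p"]
        assert res["above_level"]["adenylated"] == ["miR-1-5p"]

    def test_uniform_profiles_yield_no_flags(self):
        tissue = {"n1": "normal", "t1": "tumor"}
        by_sample = {s: [make_assignment(G1, 90), make_assignment(G1, 10, nta="A")]
                     for s in tissue}
        profiles, _ = nta_tables(by_sample)
        res = nta_screens(profiles, tissue, [("tumor", "normal")])
        assert res["shift_hits"].empty and not res["above_level"]["adenylated"]

    def test_topk_overlap_of_disjoint_lists_is_empty(self):
        tissue = {"s1": "normal"}
        by_sample = {"s1": [
            make_assignment(G1, 50), make_assignment(G1, 50, nta="A"),
            make_assignment(G2, 50), make_assignment(G2, 50, nta="T"),
        ]}
        profiles, _ = nta_tables(by_sample)
        res = nta_screens(profiles, tissue, [], top_k=1)
        assert res["top_overlap"] == []


class TestArmRatios:
    def _setup(self, ratios_by_sample):
        """ratios_by_sample: sample -> (count5, count3) for one precursor."""
        from conftest import make_precursor

        rec = make_precursor("mir-x", mature5=("miR-x-5p", "ACGTACGTACGTACGTACGTAC"),
                             mature3=("miR-x-3p", "TTGCATTGCATTGCATTGCATG"))
        g5 = MultiLocusGroup("miR-x-5p", ("mir-x",), rec.matures[0].canonical_sequence)
        g3 = MultiLocusGroup("miR-x-3p", ("mir-x",), rec.matures[1].canonical_sequence)
        by_sample, libs = {}, []
        for sample, (c5, c3) in ratios_by_sample.items():
            by_sample[sample] = [make_assignment(g5, c5), make_assignment(g3, c3)]
            libs.append(Library(sample, [], library_size=10_000))
        return by_sample, libs, [rec]

    def test_equal_arms_give_ratio_one_and_no_hits(self):
        by_sample, libs, recs = self._setup({"n1": (50, 50), "t1": (50, 50)})
        tissue = {"n1": "normal", "t1": "tumor"}
        expr = arm_expression(by_sample, libs, recs)
        res = arm_ratios(expr, tissue, [("tumor", "normal")])
        assert all(r.ratio == pytest.approx(1.0) for r in res["records"])
        assert res["screen_hits"].empty

    def test_fold_between_tissues_flags_hit_without_inversion(self):
        by_sample, libs, recs = self._setup({"n1": (320, 100), "t1": (190, 100)})
        tissue = {"n1": "normal", "t1": "tumor"}
        res = arm_ratios(arm_expression(by_sample, libs, recs), tissue,
                         [("normal", "tumor")])
        (hit,) = res["screen_hits"].to_dict("records")
        assert hit["fold"] == pytest.approx(3.2 / 1.9, rel=1e-6)
        assert res["inversions"].empty  # 5p stays dominant in both

    def test_dominant_arm_inversion_flagged(self):
        by_sample, libs, recs = self._setup({"n1": (200, 100), "t1": (100, 200)})
        tissue = {"n1": "normal", "t1": "tumor"}
        res = arm_ratios(arm_expression(by_sample, libs, recs), tissue,
                         [("tumor", "normal")])
        assert len(res["screen_hits"]) == 1
        (inv,) = res["inversions"].to_dict("records")
        assert {inv["arm_a"], inv["arm_b"]} == {"5p", "3p"}

    def test_canonical_only_mode_ignores_isomir_reads(self):
        from conftest import make_precursor

        rec = make_precursor("mir-x", mature5=("miR-x-5p", "ACGTACGTACGTACGTACGTAC"),
                             mature3=("miR-x-3p", "TTGCATTGCATTGCATTGCATG"))
        g5 = MultiLocusGroup("miR-x-5p", ("mir-x",), rec.matures[0].canonical_sequence)
        g3 = MultiLocusGroup("miR-x-3p", ("mir-x",), rec.matures[1].canonical_sequence)
        by_sample = {"s1": [make_assignment(g5, 100), make_assignment(g5, 100, offset3=1),
                            make_assignment(g3, 100)]}
        libs = [Library("s1", [], library_size=10_000)]
        all_iso = arm_expression(by_sample, libs, [rec], "all_isoforms")
        canon = arm_expression(by_sample, libs, [rec], "canonical_only")
        assert all_iso.iloc[0]["cpm_5p"] == 2 * canon.iloc[0]["cpm_5p"]

    def test_single_arm_precursor_skipped(self, toy_records, toy_groups):
        gb = next(g for g in toy_groups if g.base_name == "miR-b1-5p")
        by_sample = {"s1": [make_assignment(gb, 100)]}
        libs = [Library("s1", [], library_size=1_000)]
        expr = arm_expression(by_sample, libs, toy_records)
        assert set(expr["precursor_id"]) == {"mir-c"}  # the only both-arm precursor
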