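"""Fusion parsing, FAF arithmetic and the filter cascade."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ballistic.fusion_catalog import (
    KnowledgeTables,
    aggregate_records,
    artifact_filters,
    classify_fusion,
    compute_faf,
    evidence_filter,
    exclusivity_grouping,
    faf_threshold_filter,
    group_by_partner,
    parse_fusion_calls,
    recurrence_filters,
    run_catalog,
)

HEADER = (
    "#FusionName\tJunctionReadCount\tSpanningFragCount\tLeftGene\tLeftBreakpoint\t"
    "RightGene\tRightBreakpoint\tFFPM\tLargeAnchorSupport\tsample_id\tcohort_id\t"
    "wt5_reads\twt3_reads\n"
)


def _row(g5="A", g3="B", j=5, s=3, ffpm=1.0, anchor="YES_LDAS", sample="s1",
         cohort="c1", wt5=10, wt3=10):
    return (
        f"{g5}--{g3}\t{j}\t{s}\t{g5}\tchr1:100:+\t{g3}\tchr1:900:+\t{ffpm}\t"
        f"{anchor}\t{sample}\t{cohort}\t{wt5}\t{wt3}\n"
    )


class TestParse:
    def test_fixture_rows_parse_field_exact(self, tmp_path):
        path = tmp_path / "calls.tsv"
        rows = [
            _row(g5=f"G{i}", g3=f"H{i}", j=i + 1, s=i, ffpm=0.1 * (i + 1), sample=f"s{i}")
            for i in range(10)
        ]
        path.write_text(HEADER + "".join(rows))
        calls = parse_fusion_calls(path)
        assert len(calls) == 10
        assert calls.loc[3, "gene5"] == "G3"
        assert calls.loc[3, "junction_reads"] == 4
        assert calls.loc[3, "spanning_frags"] == 3
        assert calls.loc[3, "ffpm"] == pytest.approx(0.4)
        assert bool(calls.loc[3, "large_anchor"])
        assert calls.loc[3, "sample_id"] == "s3"

    def test_empty_file_with_header_gives_empty_table(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text(HEADER)
        assert len(parse_fusion_calls(path)) == 0

    def test_non_numeric_count_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(HEADER + _row() + _row(j="NA", sample="s2"))
        with pytest.raises(ValueError, match="line 3"):
            parse_fusion_calls(path)

    def test_missing_mandatory_column_is_listed(self, tmp_path):
        path = tmp_path / "nocol.tsv"
        path.write_text(HEADER.replace("FFPM\t", "XXX\t") + "")
        with pytest.raises(ValueError, match="FFPM"):
            parse_fusion_calls(path)

    def test_wildtype_counts_inverted_from_allele_frequencies(self, tmp_path):
        header = HEADER.replace("wt5_reads\twt3_reads", "faf_left\tfaf_right")
        row = _row(j=10, wt5="0.25", wt3="0.5")
        (tmp_path / "faf.tsv").write_text(header + row)
        calls = parse_fusion_calls(tmp_path / "faf.tsv")
        # WT = F (1 - f) / f
        assert calls.loc[0, "wt5_reads"] == 30
        assert calls.loc[0, "wt3_reads"] == 10

    def test_reciprocal_calls_kept_distinct(self, tmp_path):
        path = tmp_path / "recip.tsv"
        path.write_text(HEADER + _row(g5="A", g3="B") + _row(g5="B", g3="A"))
        calls = parse_fusion_calls(path)
        assert set(zip(calls.gene5, calls.gene3)) == {("A", "B"), ("B", "A")}


class TestEvidence:
    @pytest.mark.parametrize(
        "j,s,ffpm,anchor,expect,reason",
        [
            (1, 1, 0.1, True, True, ""),
            (5, 3, 0.05, True, False, "ffpm"),
            (0, 9, 2.0, True, False, "junction_reads"),
            (4, 0, 2.0, True, False, "spanning_frags"),
            (4, 2, 2.0, False, False, "large_anchor"),
        ],
    )
    def test_thresholds_inclusive_with_reason(self, j, s, ffpm, anchor, expect, reason):
        calls = pd.DataFrame(
            {"junction_reads": [j], "spanning_frags": [s], "ffpm": [ffpm], "large_anchor": [anchor]}
        )
        res = evidence_filter(calls)
        assert bool(res["pass"][0]) is expect
        assert res.reason[0] == reason


class TestFAF:
    def _calls(self, rows):
        return pd.DataFrame(rows, columns=["junction_reads", "wt5_reads", "wt3_reads"])

    def test_simple_fractions(self):
        out = compute_faf(self._calls([(3, 9, 9)]))
        assert (out.faf_l[0], out.faf_r[0], out.faf[0]) == (0.25, 0.25, 0.25)

    def test_zero_support_defines_faf_zero(self):
        out = compute_faf(self._calls([(0, 50, 50), (0, 0, 0)]))
        assert (out.faf == 0).all()

    def test_matches_one_line_formula_on_random_tuples(self):
        rng = np.random.default_rng(0)
        f = rng.integers(0, 50, 1000)
        wt5 = rng.integers(0, 200, 1000)
        wt3 = rng.integers(0, 200, 1000)
        out = compute_faf(self._calls(list(zip(f, wt5, wt3))))
        # independent one-line evaluation
        l = np.where(f + wt5 > 0, f / (f + wt5), 0)
        r = np.where(f + wt3 > 0, f / (f + wt3), 0)
        expect = (l + r) / 2
        assert np.max(np.abs(out.faf.to_numpy() - expect)) < 1e-12
        assert ((out.faf >= 0) & (out.faf <= 1)).all()

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 100), st.integers(0, 300), st.integers(0, 300))
    def test_partner_swap_invariance_and_range(self, f, a, b):
        fwd = compute_faf(self._calls([(f, a, b)]))
        rev = compute_faf(self._calls([(f, b, a)]))
        assert fwd.faf[0] == rev.faf[0]
        assert 0 <= fwd.faf[0] <= 1

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            compute_faf(self._calls([(-1, 5, 5)]))


def _calls_frame(rows):
    df = pd.DataFrame(rows, columns=["sample_id", "cohort_id", "gene5", "gene3"])
    df["junction_reads"] = 10
    df["spanning_frags"] = 5
    df["ffpm"] = 1.0
    df["large_anchor"] = True
    df["wt5_reads"] = 20
    df["wt3_reads"] = 20
    df["left_breakpoint"] = "chr1:100:+"
    df["right_breakpoint"] = "chr1:900:+"
    return df


class TestArtifactFilters:
    def test_promiscuous_gene_loses_all_its_calls_in_the_sample(self):
        calls = _calls_frame([("s1", "c1", "A", "B"), ("s1", "c1", "A", "C")])
        fail = artifact_filters(calls, KnowledgeTables())
        assert fail.promiscuity.all()

    def test_reciprocal_pair_alone_is_exempt(self):
        calls = _calls_frame([("s1", "c1", "A", "B"), ("s1", "c1", "B", "A")])
        fail = artifact_filters(calls, KnowledgeTables())
        assert not fail.promiscuity.any()

    def test_pseudogene_partner_removed(self):
        calls = _calls_frame([("s1", "c1", "PSG1", "B")])
        fail = artifact_filters(calls, KnowledgeTables(pseudogenes={"PSG1"}))
        assert fail.pseudogene.all()

    def test_ig_filter_needs_both_partners(self):
        kt = KnowledgeTables(ig_hb_genes={"IGHM", "IGKC"})
        both = artifact_filters(_calls_frame([("s1", "c1", "IGHM", "IGKC")]), kt)
        one = artifact_filters(_calls_frame([("s1", "c1", "IGHM", "B")]), kt)
        assert both.immunoglobulin.all() and not one.immunoglobulin.any()

    def test_artifact_block_is_order_invariant(self, default_bundle):
        """Filters are evaluated independently, so any application order
        yields the same survivor set."""
        calls = default_bundle.fusion_calls
        fail = artifact_filters(calls, default_bundle.knowledge)
        survivors = set(calls.index[~fail.any(axis=1)])
        for order in itertools.permutations(fail.columns):
            alive = set(calls.index)
            for f in order:
                alive -= set(calls.index[fail[f]])
            assert alive == survivors


class TestRecurrenceAndFAFThresholds:
    def test_known_leukemia_fusion_still_needs_five_patients(self):
        rows = [(f"s{i}", f"c{i % 2}", "KMT2A", "AFF1") for i in range(4)]
        records = aggregate_records(_calls_frame(rows))
        kt = KnowledgeTables(leukemia_genes={"KMT2A"})
        fail = recurrence_filters(records, kt, min_patients=5)
        assert fail.min_patients.all()
        assert not fail.single_project.any()  # rescued from the other filters

    def test_single_project_fusion_dropped(self):
        rows = [(f"s{i}", "c1", "A", "B") for i in range(6)]
        records = aggregate_records(_calls_frame(rows))
        fail = recurrence_filters(records, KnowledgeTables(), min_patients=5)
        assert fail.single_project.all()

    def test_normal_panel_dropped_unless_rescued(self):
        rows = [(f"s{i}", f"c{i % 2}", "A", "B") for i in range(6)]
        records = aggregate_records(_calls_frame(rows))
        kt = KnowledgeTables(normal_panel_pairs={frozenset(("A", "B"))})
        assert recurrence_filters(records, kt).normal_panel.all()
        kt2 = KnowledgeTables(
            normal_panel_pairs={frozenset(("A", "B"))}, leukemia_genes={"A"}
        )
        assert not recurrence_filters(records, kt2).normal_panel.any()

    def test_min_patients_config_error(self):
        records = aggregate_records(_calls_frame([("s1", "c1", "A", "B")]))
        with pytest.raises(ValueError, match="min_patients"):
            recurrence_filters(records, KnowledgeTables(), min_patients=0)

    def test_median_faf_strictly_above_threshold(self):
        rec = pd.DataFrame(
            {
                "median_faf": [0.08, 0.25, 0.1],
                "median_faf_l": [0.05, 0.02, 0.3],
                "median_faf_r": [0.10, 0.40, 0.3],
            }
        )
        fail = faf_threshold_filter(rec)
        assert list(fail.faf_median) == [True, False, True]  # 0.1 exactly fails (strict >)

    def test_partner_median_uses_lower_side_inclusive(self):
        rec = pd.DataFrame(
            {
                "median_faf": [0.3, 0.3],
                "median_faf_l": [0.02, 0.005],
                "median_faf_r": [0.4, 0.4],
            }
        )
        fail = faf_threshold_filter(rec)
        assert list(fail.faf_partner) == [False, True]


class TestClassifyAndGroup:
    def test_class_precedence_and_unordered_matching(self):
        kt = KnowledgeTables(
            known_fusions={frozenset(("A", "B")): "ALL", frozenset(("C", "D")): "solid"}
        )
        assert classify_fusion("A", "B", kt) == "ALL"
        assert classify_fusion("B", "A", kt) == "ALL"  # reciprocal
        assert classify_fusion("C", "D", kt) == "solid"
        assert classify_fusion("X", "Y", kt) == "novel"

    def test_group_label_follows_most_recurrent_partner(self):
        records = pd.DataFrame(
            {
                "gene5": ["KMT2A", "KMT2A", "AFF1"],
                "gene3": ["AFF1", "MLLT3", "ZZZ"],
                "n_patients": [50, 30, 10],
            }
        )
        groups = group_by_partner(records)
        assert list(groups) == ["KMT2A-r", "KMT2A-r", "AFF1-r"]

    def test_tie_breaks_lexicographically(self):
        records = pd.DataFrame({"gene5": ["XYZ"], "gene3": ["ABC"], "n_patients": [10]})
        assert group_by_partner(records)[0] == "ABC-r"


class TestExclusivity:
    def test_perfectly_exclusive_groups_retained(self):
        pres = pd.DataFrame(
            np.vstack([np.r_[np.ones(50), np.zeros(50)], np.r_[np.zeros(50), np.ones(50)]]).astype(int),
            index=["g1", "g2"],
            columns=[f"s{i}" for i in range(100)],
        )
        labels = exclusivity_grouping(pres)
        assert list(labels) == ["g1", "g2"]

    def test_independent_group_collapses_to_other(self):
        rng = np.random.default_rng(0)
        a = np.r_[np.ones(50), np.zeros(50)].astype(int)
        b = 1 - a
        c = rng.integers(0, 2, 100)  # independent of both
        pres = pd.DataFrame([a, b, c], index=["g1", "g2", "g3"], columns=[f"s{i}" for i in range(100)])
        labels = exclusivity_grouping(pres)
        assert labels["g1"] == "g1" and labels["g2"] == "g2"
        assert labels["g3"] == "Other"

    def test_single_sample_group_warns_and_collapses(self):
        pres = pd.DataFrame(
            [[1, 1, 1, 0, 0, 0], [0, 0, 0, 0, 0, 1]], index=["g1", "g2"],
            columns=[f"s{i}" for i in range(6)],
        )
        with pytest.warns(UserWarning, match="g2"):
            labels = exclusivity_grouping(pres)
        assert labels["g2"] == "Other"


class TestCascade:
    def test_filters_are_monotone_and_trail_complete(self, default_bundle, default_catalog):
        calls = default_bundle.fusion_calls
        res = default_catalog
        assert len(res.surviving_calls) <= len(calls)
        assert len(res.trail) == len(calls)
        removed = res.trail.removed_by != ""
        survivors = set(
            zip(res.surviving_calls.sample_id, res.surviving_calls.gene5 + "::" + res.surviving_calls.gene3)
        )
        for _, row in res.trail[removed].iterrows():
            assert (row.sample_id, row.fusion_id) not in survivors

    def test_survivors_match_truth_ledger(self, default_bundle, default_catalog):
        truth = {f for fl in default_bundle.ledger.true_fusions_by_sample.values() for f in fl}
        assert set(default_catalog.records.fusion_id) == truth
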