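"""Event enumeration, PSI arithmetic, imputation, differential splicing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ballistic._stats import logit
from ballistic.annotation import AnnotationBundle, Transcript
from ballistic.splicing_events import (
    binarize_inclusion,
    compute_psi,
    diff_splice,
    filter_and_impute,
    generate_events,
    psi_expression_correlation,
)


class TestGenerateEvents:
    def test_toy_annotation_yields_each_type_once(self, toy_annotation):
        events = generate_events(toy_annotation)
        by_type = {}
        for e in events:
            by_type.setdefault(e.etype, []).append(e)
        assert {t: len(v) for t, v in sorted(by_type.items())} == {
            "A3": 1, "A5": 1, "AF": 1, "AL": 1, "MX": 1, "RI": 1, "SE": 2
        }
        # hand-written signatures for the defining cases
        ids = {e.event_id for e in events}
        assert "gSE;SE:chrT:100-201:250-301:+" in ids
        assert "gRI;RI:chrT:451:500-541:600:+" in ids
        assert "gA3;A3:chrT:700-801:700-821:+" in ids
        assert "gA5;A5:chrT:1050-1151:1070-1151:+" in ids
        assert "gMX;MX:chrT:1420-1451:1500-1651:1420-1551:1600-1651:+" in ids
        assert "gAF;AF:chrT:1801:1850-2001:1901:1950-2001:+" in ids
        assert "gAL;AL:chrT:2250-2301:2350:2250-2401:2450:+" in ids
        assert "gNEG;SE:chrT:2700-2801:2850-2901:-" in ids

    def test_single_isoform_gene_yields_no_events(self, toy_annotation):
        events = generate_events(toy_annotation)
        assert not any(e.gene_id == "gONE" for e in events)

    def test_membership_sets_are_consistent(self, toy_annotation):
        for e in generate_events(toy_annotation):
            assert set(e.inclusion_transcripts) < set(e.total_transcripts)
            assert len(e.inclusion_transcripts) >= 1

    def test_transcript_order_does_not_matter(self, toy_annotation):
        events = generate_events(toy_annotation)
        reordered = AnnotationBundle(
            genes=toy_annotation.genes,
            transcripts=dict(reversed(list(toy_annotation.transcripts.items()))),
            domains=toy_annotation.domains,
            sequences=toy_annotation.sequences,
        )
        again = generate_events(reordered)
        assert [e.event_id for e in events] == [e.event_id for e in again]

    def test_malformed_transcript_skips_gene_with_warning(self, toy_annotation):
        bad = Transcript.__new__(Transcript)
        bad.transcript_id, bad.gene_id = "tBAD", "gSE"
        bad.exons = [(1, 100), (50, 150)]  # overlapping, bypassing validation
        bad.cds_start = bad.cds_end = None
        txs = dict(toy_annotation.transcripts)
        txs["tBAD"] = bad
        broken = AnnotationBundle(
            genes=toy_annotation.genes, transcripts=txs,
            domains=toy_annotation.domains, sequences=toy_annotation.sequences,
        )
        with pytest.warns(UserWarning, match="gSE"):
            events = generate_events(broken)
        assert not any(e.gene_id == "gSE" for e in events)
        assert any(e.gene_id == "gRI" for e in events)


class TestPSI:
    def _se_events(self, toy_annotation):
        return [e for e in generate_events(toy_annotation) if e.event_id.startswith("gSE")]

    def test_inclusion_ratio_arithmetic(self, toy_annotation):
        ev = self._se_events(toy_annotation)
        tpm = pd.DataFrame(
            {"s1": {t: 0.0 for t in toy_annotation.transcripts}}
        )
        tpm.loc["tSE.1", "s1"] = 3.0
        tpm.loc["tSE.2", "s1"] = 1.0
        psi = compute_psi(ev, tpm)
        assert psi.loc["gSE;SE:chrT:100-201:250-301:+", "s1"] == pytest.approx(0.75)

    def test_low_total_tpm_is_missing(self, toy_annotation):
        ev = self._se_events(toy_annotation)
        tpm = pd.DataFrame({"s1": {t: 0.0 for t in toy_annotation.transcripts}})
        tpm.loc["tSE.1", "s1"] = 0.5
        tpm.loc["tSE.2", "s1"] = 0.3
        psi = compute_psi(ev, tpm)
        assert psi.loc["gSE;SE:chrT:100-201:250-301:+", "s1"] != psi.loc[
            "gSE;SE:chrT:100-201:250-301:+", "s1"
        ]  # NaN

    def test_missing_transcript_raises(self, toy_annotation):
        ev = self._se_events(toy_annotation)
        tpm = pd.DataFrame({"s1": {"tSE.1": 1.0}})
        with pytest.raises(ValueError, match="tSE.2"):
            compute_psi(ev, tpm)

    def test_two_isoform_complement_identity_exact(self, default_bundle):
        """PSI of the inclusion isoform plus the exclusion fraction is 1."""
        b = default_bundle
        eids = b.ledger.event_ids_planted_dpsi[:10]
        for eid in eids:
            gid = eid.split(";")[0]
            inc, exc = b.tpm.loc[f"{gid}.t1"], b.tpm.loc[f"{gid}.t2"]
            tot = inc + exc
            ok = tot >= 1.0
            psi = inc[ok] / tot[ok]
            psi_c = exc[ok] / tot[ok]
            # exact up to one ulp of the two divisions
            assert np.max(np.abs(psi + psi_c - 1.0)) <= 1e-12


class TestFilterImpute:
    def _psi(self, arr):
        return pd.DataFrame(
            arr, index=[f"e{i}" for i in range(len(arr))],
            columns=[f"s{i}" for i in range(len(arr[0]))],
        )

    def test_event_missing_in_11_percent_dropped(self):
        rng = np.random.default_rng(17)
        base = rng.uniform(0.2, 0.8, (20, 100))
        psi = self._psi(base)
        psi.iloc[0, :11] = np.nan  # 11% > 10%
        psi.iloc[1, :10] = np.nan  # exactly 10% stays
        out = filter_and_impute(psi, k=5)
        assert "e0" not in out.index and "e1" in out.index
        assert not out.isna().any().any()

    def test_complete_matrix_unchanged(self):
        rng = np.random.default_rng(18)
        psi = self._psi(rng.uniform(0, 1, (15, 10)))
        pd.testing.assert_frame_equal(filter_and_impute(psi, k=5), psi)

    def test_forced_neighbor_reproduces_duplicate_value(self):
        rng = np.random.default_rng(19)
        row = rng.uniform(0.2, 0.8, 30)
        others = rng.uniform(0.2, 0.8, (10, 30))
        psi = self._psi(np.vstack([row, row, others]))
        psi.iloc[0, 5] = np.nan  # its duplicate e1 is the nearest neighbor
        out = filter_and_impute(psi, k=1)
        assert out.iloc[0, 5] == pytest.approx(row[5], abs=1e-12)

    def test_observed_entries_never_altered_and_bounds_respected(self):
        rng = np.random.default_rng(20)
        psi = self._psi(rng.uniform(0, 1, (25, 40)))
        mask = rng.random((25, 40)) < 0.05
        holes = psi.where(~mask)
        out = filter_and_impute(holes, k=5)
        kept = out.index
        observed = ~holes.loc[kept].isna()
        assert np.allclose(out[observed].fillna(0), holes.loc[kept][observed].fillna(0))
        assert ((out >= 0) & (out <= 1)).all().all()

    def test_k_not_smaller_than_events_rejected(self):
        psi = self._psi(np.full((3, 4), 0.5))
        with pytest.raises(ValueError, match="k="):
            filter_and_impute(psi, k=3)


class TestDiffSplice:
    def _groups(self, n):
        return pd.Series(
            ["high"] * n + ["low"] * n, index=[f"s{i}" for i in range(2 * n)]
        )

    def test_reduces_to_t_test_without_covariates(self):
        rng = np.random.default_rng(21)
        psi = pd.DataFrame(
            rng.beta(5, 5, (30, 40)), index=[f"e{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(40)],
        )
        res = diff_splice(psi, self._groups(20), sd_min=0.0).set_index("event_id")
        y = logit(psi.to_numpy(), eps=0.01)
        for i, e in enumerate(psi.index):
            t, p = stats.ttest_ind(y[i, 20:], y[i, :20], equal_var=True)
            assert res.loc[e, "p"] == pytest.approx(p, abs=1e-10)

    def test_constant_event_removed_by_sd_filter(self):
        rng = np.random.default_rng(22)
        psi = pd.DataFrame(
            np.vstack([np.full(40, 0.5), rng.beta(2, 2, (5, 40))]),
            index=[f"e{i}" for i in range(6)], columns=[f"s{i}" for i in range(40)],
        )
        res = diff_splice(psi, self._groups(20))
        assert "e0" not in set(res.event_id)

    def test_planted_shift_has_power(self):
        rng = np.random.default_rng(23)
        n = 50
        # planted events: tight beta noise around shifted group means;
        # null events: wider noise so they survive the SD >= 0.1 filter
        mu = np.tile(rng.uniform(0.3, 0.7, 60)[:, None], (1, 2 * n))
        mu[:30] = 0.35
        mu[:30, :n] += 0.3
        conc = np.r_[np.full(30, 50.0), np.full(30, 10.0)][:, None]
        psi = pd.DataFrame(
            rng.beta(mu * conc, (1 - mu) * conc), index=[f"e{i}" for i in range(60)],
            columns=[f"s{i}" for i in range(2 * n)],
        )
        res = diff_splice(psi, self._groups(n)).set_index("event_id")
        planted = [f"e{i}" for i in range(30)]
        assert res.loc[planted, "significant"].mean() >= 0.8
        null = [e for e in res.index if int(e[1:]) >= 30]
        assert len(null) >= 20  # nulls survive the SD filter
        assert res.loc[null, "significant"].mean() <= 0.05

    def test_significance_stable_under_epsilon_choice(self):
        rng = np.random.default_rng(24)
        n = 30
        mu = np.full((40, 2 * n), 0.4)
        mu[:10, :n] += 0.3
        psi = pd.DataFrame(
            rng.beta(mu * 40, (1 - mu) * 40), index=[f"e{i}" for i in range(40)],
            columns=[f"s{i}" for i in range(2 * n)],
        )
        a = diff_splice(psi, self._groups(n), eps=0.01).set_index("event_id").significant
        b = diff_splice(psi, self._groups(n), eps=0.001).set_index("event_id").significant
        assert (a == b).all()

    def test_confounded_covariate_rejected(self):
        psi = pd.DataFrame(
            np.random.default_rng(25).beta(2, 2, (15, 20)),
            index=[f"e{i}" for i in range(15)], columns=[f"s{i}" for i in range(20)],
        )
        groups = self._groups(10)
        cov = pd.DataFrame({"batch": ["x"] * 10 + ["y"] * 10}, index=groups.index)
        with pytest.raises(ValueError, match="aliased|rank"):
            diff_splice(psi, groups, covariates=cov)


class TestBinarizeAndCorrelation:
    def test_strict_threshold(self):
        psi = pd.DataFrame({"s1": [0.51, 0.5, 0.4]}, index=["e1", "e2", "e3"])
        out = binarize_inclusion(psi)
        assert list(out.s1) == [1, 0, 0]

    def test_affine_psi_expression_gives_unit_correlation(self):
        rng = np.random.default_rng(26)
        x = rng.uniform(2, 8, 30)
        psi = pd.DataFrame([0.05 * x + 0.1], index=["e1"], columns=[f"s{i}" for i in range(30)])
        expr = pd.DataFrame([x], index=["g1"], columns=psi.columns)
        table, frac = psi_expression_correlation(psi, expr, pd.Series({"e1": "g1"}))
        assert table.r[0] == pytest.approx(1.0, abs=1e-12)
        assert frac == 1.0

    def test_matches_brute_force_covariance_formula(self):
        rng = np.random.default_rng(27)
        x = rng.uniform(0, 1, 25)
        y = rng.uniform(2, 9, 25)
        psi = pd.DataFrame([x], index=["e1"], columns=[f"s{i}" for i in range(25)])
        expr = pd.DataFrame([y], index=["g1"], columns=psi.columns)
        table, _ = psi_expression_correlation(psi, expr, pd.Series({"e1": "g1"}))
        num = np.mean((x - x.mean()) * (y - y.mean()))
        expect = num / (x.std() * y.std())
        assert table.r[0] == pytest.approx(expect, rel=1e-12)

    def test_zero_variance_excluded_with_note(self):
        psi = pd.DataFrame([np.full(10, 0.5)], index=["e1"], columns=[f"s{i}" for i in range(10)])
        expr = pd.DataFrame([np.arange(10.0)], index=["g1"], columns=psi.columns)
        table, frac = psi_expression_correlation(psi, expr, pd.Series({"e1": "g1"}))
        assert np.isnan(table.r[0]) and table.note[0] == "zero variance"
        assert np.isnan(frac)

    def test_independent_pairs_average_near_zero(self):
        rng = np.random.default_rng(28)
        n_ev = 200
        psi = pd.DataFrame(
            rng.uniform(0, 1, (n_ev, 50)), index=[f"e{i}" for i in range(n_ev)],
            columns=[f"s{i}" for i in range(50)],
        )
        expr = pd.DataFrame(
            rng.normal(5, 1, (n_ev, 50)), index=[f"g{i}" for i in range(n_ev)],
            columns=psi.columns,
        )
        gene_map = pd.Series({f"e{i}": f"g{i}" for i in range(n_ev)})
        table, _ = psi_expression_correlation(psi, expr, gene_map)
        assert abs(table.r.mean()) < 0.05
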