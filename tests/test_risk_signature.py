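"""Signature cascade gates, Cox filtering, LOO k-scores and evaluation."""

import numpy as np
import pandas as pd
import pytest

from ballistic.risk_signature import (
    apply_model,
    cox_filter,
    evaluate,
    select_candidates,
    threshold_sweep,
    train_and_score_loo,
    train_model,
    variability_filter,
)

SETS = {"myc": ["gA", "gB"], "translation": ["gC"], "sf_rbp": ["gD"]}


class TestSelect:
    def _series(self, d):
        return pd.Series(d)

    def test_gene_passing_both_contrasts_and_membership_selected(self):
        rel = self._series({"gA": 0.6, "gB": 0.6, "gZ": 0.9})
        fus = self._series({"gA": 0.7, "gB": 0.4, "gZ": 0.9})
        # gZ passes both gates but belongs to no set; gB fails the fusion gate
        assert select_candidates(rel, fus, SETS) == ["gA"]

    def test_empty_selection_is_a_hard_error(self):
        rel = self._series({"gA": 0.1})
        fus = self._series({"gA": 0.1})
        with pytest.raises(ValueError, match="candidate"):
            select_candidates(rel, fus, SETS)

    def test_planted_signature_recovered_on_synthetic_cohort(self, default_bundle, risk_inputs):
        cands = select_candidates(
            risk_inputs["lfc_relapse"], risk_inputs["lfc_fusion"], default_bundle.gene_sets
        )
        prog = set(default_bundle.ledger.prognostic_gene_ids)
        assert len(set(cands) & prog) / len(prog) >= 0.90


def _survival_frame(x, seed, hr_per_sd=2.0, follow_up=3000.0):
    """Exponential EFS with log-hazard = log(hr) * standardized expression."""
    rng = np.random.default_rng(seed)
    n = len(x)
    lam = np.log(2) / 900 * np.exp(np.log(hr_per_sd) * (x - x.mean()) / x.std())
    t = rng.exponential(1 / lam)
    cens = np.minimum(rng.uniform(500, follow_up, n), follow_up)
    return pd.DataFrame(
        {
            "efs_time_days": np.minimum(t, cens),
            "relapse": (t <= cens).astype(int),
            "age_years": rng.uniform(1, 18, n),
            "sex": rng.choice(["M", "F"], n),
        },
        index=[f"s{i}" for i in range(n)],
    )


class TestCoxFilter:
    def test_planted_hazard_gene_has_power(self):
        kept = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            x = rng.normal(0, 1, 130)
            clin = _survival_frame(x, seed=1000 + rep)
            expr = pd.DataFrame([x], index=["g"], columns=clin.index)
            res = cox_filter(["g"], expr, clin)
            kept += int(res.kept[0])
        assert kept / 20 >= 0.8

    def test_null_gene_keeps_nominal_rate(self):
        kept = 0
        reps = 60
        for rep in range(reps):
            rng = np.random.default_rng(5000 + rep)
            x = rng.normal(0, 1, 130)
            clin = _survival_frame(rng.normal(0, 1, 130), seed=2000 + rep)
            expr = pd.DataFrame([x], index=["g"], columns=clin.index)
            kept += int(cox_filter(["g"], expr, clin).kept[0])
        # binomial 95% acceptance region around 0.05
        assert 0 <= kept / reps <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / reps) + 0.02

    def test_constant_expression_flagged_not_fitted(self):
        clin = _survival_frame(np.random.default_rng(0).normal(0, 1, 40), seed=3)
        expr = pd.DataFrame([np.ones(40)], index=["g"], columns=clin.index)
        res = cox_filter(["g"], expr, clin)
        assert not res.kept[0] and "constant" in res.reason[0]

    def test_zero_events_is_a_hard_error(self):
        clin = _survival_frame(np.random.default_rng(0).normal(0, 1, 30), seed=4)
        clin["relapse"] = 0
        expr = pd.DataFrame([np.arange(30.0)], index=["g"], columns=clin.index)
        with pytest.raises(ValueError, match="events"):
            cox_filter(["g"], expr, clin)


class TestVariability:
    def _setup(self, means_by_cohort):
        cohorts, cols, vals = [], [], []
        for c, m in means_by_cohort.items():
            for i in range(5):
                cols.append(f"{c}_{i}")
                cohorts.append(c)
                vals.append(m)
        expr = pd.DataFrame([vals], index=["g"], columns=cols)
        return expr, pd.Series(cohorts, index=cols)

    def test_spread_above_three_removed(self):
        expr, cohorts = self._setup({"c1": 5.0, "c2": 5.5, "c3": 8.2})
        res = variability_filter(["g"], expr, cohorts)
        assert not res.kept[0] and res.max_cohort_logfc[0] == pytest.approx(3.2)

    def test_equal_means_kept(self):
        expr, cohorts = self._setup({"c1": 5.0, "c2": 5.0})
        assert variability_filter(["g"], expr, cohorts).kept[0]

    def test_39_candidates_with_two_unstable_yield_37(self):
        rng = np.random.default_rng(13)
        cols = [f"c{c}_{i}" for c in range(3) for i in range(4)]
        cohorts = pd.Series([c.split("_")[0] for c in cols], index=cols)
        base = rng.normal(6, 0.2, (39, len(cols)))
        expr = pd.DataFrame(base, index=[f"g{i}" for i in range(39)], columns=cols)
        expr.loc["g5", cohorts == "c2"] += 4.0  # unstable across datasets
        expr.loc["g21", cohorts == "c0"] -= 3.5
        res = variability_filter(list(expr.index), expr, cohorts)
        assert res.kept.sum() == 37
        assert set(res.loc[~res.kept, "gene_id"]) == {"g5", "g21"}


class TestLOO:
    def _separable(self, n=24):
        rng = np.random.default_rng(14)
        y = pd.Series(np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int),
                      index=[f"s{i}" for i in range(n)])
        x = np.vstack([rng.normal(y.to_numpy() * 8, 0.2, n) for _ in range(5)])
        return pd.DataFrame(x, index=[f"g{i}" for i in range(5)], columns=y.index), y

    def test_unanimous_votes_give_unit_k_score(self):
        expr, y = self._separable()
        sc = train_and_score_loo(expr, y, n_trees=50, seed=0)
        assert sc.loc[y == 1, "k_score"].min() == 1.0
        assert sc.loc[y == 0, "k_score"].max() == 0.0
        assert (sc.loc[y == 1, "risk_class"] == "high").all()

    def test_fixed_seed_reproduces_scores_exactly(self, default_logcpm, default_bundle):
        genes = default_bundle.ledger.prognostic_gene_ids[:10]
        train = default_bundle.clinical.index[default_bundle.clinical.cohort == "cohort01"][:30]
        labels = default_bundle.clinical.loc[train, "relapse"]
        a = train_and_score_loo(default_logcpm.loc[genes, train], labels, n_trees=60, seed=5)
        b = train_and_score_loo(default_logcpm.loc[genes, train], labels, n_trees=60, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_single_class_labels_rejected(self):
        expr, y = self._separable()
        with pytest.raises(ValueError, match="single class|single-class"):
            train_and_score_loo(expr, pd.Series(1, index=y.index), n_trees=10)


class TestEvaluate:
    def test_perfect_separation_gives_auc_one(self):
        scores = pd.Series([0.9, 0.8, 0.2, 0.1], index=list("abcd"))
        labels = pd.Series([1, 1, 0, 0], index=list("abcd"))
        assert evaluate(scores, labels)["auc"] == 1.0

    def test_random_scores_give_auc_near_half(self):
        rng = np.random.default_rng(15)
        idx = [f"s{i}" for i in range(2000)]
        scores = pd.Series(rng.uniform(0, 1, 2000), index=idx)
        labels = pd.Series(rng.integers(0, 2, 2000), index=idx)
        assert abs(evaluate(scores, labels)["auc"] - 0.5) < 0.05

    def test_logrank_matches_hand_computation_on_six_subjects(self):
        # high: events at 1, 3; censored 5.  low: events at 2, 4, 6.
        idx = list("abcdef")
        scores = pd.Series([0.9, 0.9, 0.9, 0.1, 0.1, 0.1], index=idx)
        labels = pd.Series([1, 1, 0, 1, 1, 1], index=idx)
        times = pd.Series([1, 3, 5, 2, 4, 6], index=idx)
        events = pd.Series([1, 1, 0, 1, 1, 1], index=idx)
        res = evaluate(scores, labels, times, events, threshold=0.5)
        # hand computation of the log-rank statistic, step by step:
        # t=1: n=6 (3 high), d=1 -> E_high=0.5, V=0.25
        # t=2: n=5 (2 high), d=1 -> E_high=0.4, V=0.24
        # t=3: n=4 (2 high), d=1 -> E_high=0.5, V=0.25
        # t=4: n=3 (1 high), d=1 -> E_high=1/3, V=2/9
        # t=6: n=1 (0 high), d=1 -> E_high=0,   V=0
        o_minus_e = (1 - 0.5) + (0 - 0.4) + (1 - 0.5) + (0 - 1 / 3) + 0.0
        v = 0.25 + 0.24 + 0.25 + 2 / 9
        expect = o_minus_e**2 / v
        assert res["logrank_stat"] == pytest.approx(expect, rel=1e-6)

    def test_single_class_threshold_skips_km_keeps_roc(self):
        idx = list("abcd")
        scores = pd.Series([0.2, 0.3, 0.1, 0.4], index=idx)
        labels = pd.Series([1, 0, 1, 0], index=idx)
        times = pd.Series([1, 2, 3, 4], index=idx)
        with pytest.warns(UserWarning, match="empty"):
            res = evaluate(scores, labels, times, labels, threshold=0.9)
        assert res["km"] is None and res["roc"] is not None


class TestApplyModel:
    def test_full_model_scores_track_loo_ordering(self, default_logcpm, default_bundle):
        b = default_bundle
        genes = b.ledger.prognostic_gene_ids
        train = b.clinical.index[b.clinical.cohort == "cohort01"]
        labels = b.clinical.loc[train, "relapse"]
        loo = train_and_score_loo(default_logcpm.loc[genes, train], labels, n_trees=100, seed=3)
        model = train_model(default_logcpm.loc[genes, train], labels, n_trees=100, seed=3)
        full = apply_model(model, default_logcpm.loc[genes, train])
        rho = pd.concat([loo.k_score, full.k_score], axis=1, keys=["loo", "full"]).corr(
            method="spearman"
        ).iloc[0, 1]
        assert rho >= 0.9

    def test_high_risk_stratum_scores_dominate(self, default_logcpm, default_bundle):
        b = default_bundle
        genes = b.ledger.prognostic_gene_ids
        train = b.clinical.index[b.clinical.cohort == "cohort01"]
        model = train_model(
            default_logcpm.loc[genes, train], b.clinical.loc[train, "relapse"], n_trees=100, seed=3
        )
        rest = b.clinical.index[b.clinical.cohort != "cohort01"]
        scores = apply_model(model, default_logcpm.loc[genes, rest]).k_score
        risk = pd.Series(b.ledger.risk_labels).loc[rest]
        hi, lo = scores[risk == "high"], scores[risk == "low"]
        assert hi.median() > lo.median()
        assert hi.quantile(0.25) > lo.quantile(0.75)

    def test_empty_matrix_rejected(self, default_logcpm, default_bundle):
        b = default_bundle
        genes = b.ledger.prognostic_gene_ids
        train = b.clinical.index[b.clinical.cohort == "cohort01"]
        model = train_model(default_logcpm.loc[genes, train], b.clinical.loc[train, "relapse"],
                            n_trees=20, seed=1)
        with pytest.raises(ValueError, match="empty"):
            apply_model(model, default_logcpm.loc[genes, []])

    def test_missing_gene_tolerance(self, default_logcpm, default_bundle):
        b = default_bundle
        genes = b.ledger.prognostic_gene_ids  # 40 genes
        train = b.clinical.index[b.clinical.cohort == "cohort01"]
        model = train_model(default_logcpm.loc[genes, train], b.clinical.loc[train, "relapse"],
                            n_trees=20, seed=1)
        with pytest.warns(UserWarning, match="mean-imputed"):
            out = apply_model(model, default_logcpm.loc[genes[2:], train])  # 2/40 = 5%
        assert len(out) == len(train)
        with pytest.raises(ValueError, match="10%"):
            apply_model(model, default_logcpm.loc[genes[10:], train])  # 25% missing


def test_sensitivity_never_increases_with_threshold():
    rng = np.random.default_rng(16)
    idx = [f"s{i}" for i in range(300)]
    scores = pd.Series(rng.uniform(0, 1, 300), index=idx)
    labels = pd.Series(rng.integers(0, 2, 300), index=idx)
    sweep = threshold_sweep(scores, labels)
    sens = sweep.sensitivity.to_numpy()
    assert (np.diff(sens) <= 1e-12).all()
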