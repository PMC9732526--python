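"""Relapse-risk gene signature and tree-ensemble k-score model.

Signature construction cascade: candidate genes must show
log2FC > 0.5 both between relapse and non-relapse patients (training
cohort) and between KMT2A-r and ETV6-r patients (all other cohorts), and
belong to at least one of three sets (MYC targets, translation GO,
splicing factors/RBPs). Candidates are then filtered by a per-gene Cox
proportional-hazards model of event-free survival adjusted for age and
sex (Wald p < 0.05 on the expression coefficient) and by cross-cohort
stability (max pairwise difference of cohort mean logCPM <= 3).

The risk model is a 400-tree random forest with 4 candidate features per
split; the k-score of a sample is the fraction of trees voting the
relapse class, and k >= 0.7 classifies the sample high-risk. Evaluation
is leave-one-out (feature selection fixed once, as for a frozen
signature): per-sample held-out k-scores, ROC/AUC, Kaplan-Meier curves
and the two-group log-rank test at the 0.7 split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "select_candidates",
    "cox_filter",
    "variability_filter",
    "RiskModel",
    "train_model",
    "train_and_score_loo",
    "apply_model",
    "evaluate",
    "threshold_sweep",
]


def select_candidates(
    logfc_relapse: pd.Series,
    logfc_fusion: pd.Series,
    gene_sets: dict,
    logfc_min: float = 0.5,
) -> list:
    """Genes over-expressed in both contrasts and in >= 1 target set."""
    union = set()
    for members in gene_sets.values():
        union.update(members)
    common = logfc_relapse.index.intersection(logfc_fusion.index)
    chosen = [
        g
        for g in common
        if logfc_relapse[g] > logfc_min and logfc_fusion[g] > logfc_min and g in union
    ]
    if not chosen:
        raise ValueError(
            "no candidate genes pass the two-contrast/set-membership gate; "
            "check contrast effect sizes or gene-set files"
        )
    return sorted(chosen)


def cox_filter(
    candidates: list,
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Cox PH fit of EFS on expression + age + sex; Wald filter.

    ``clinical`` needs efs_time_days, relapse, age_years, sex. Returns a
    table with coefficient, hazard ratio, Wald p and a kept flag;
    non-converging or non-identifiable genes are flagged and excluded.
    """
    samples = expr.columns.intersection(clinical.index)
    cl = clinical.loc[samples]
    if cl.relapse.sum() == 0:
        raise ValueError("no relapse events in the training samples")
    base = pd.DataFrame(
        {
            "time": cl.efs_time_days.astype(float),
            "event": cl.relapse.astype(int),
            "age": cl.age_years.astype(float),
            "sex": (cl.sex == "M").astype(float),
        },
        index=samples,
    )
    rows = []
    for g in candidates:
        x = expr.loc[g, samples].astype(float)
        if x.std() == 0:
            rows.append({"gene_id": g, "coef": np.nan, "hr": np.nan, "p": np.nan,
                         "kept": False, "reason": "constant expression"})
            continue
        df = base.assign(x=(x - x.mean()) / x.std())
        try:
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
            coef = float(cph.params_["x"])
            p = float(cph.summary.loc["x", "p"])
            rows.append({"gene_id": g, "coef": coef, "hr": float(np.exp(coef)), "p": p,
                         "kept": p < alpha, "reason": "" if p < alpha else "wald"})
        except (ConvergenceError, ValueError) as exc:
            rows.append({"gene_id": g, "coef": np.nan, "hr": np.nan, "p": np.nan,
                         "kept": False, "reason": f"non-convergence: {exc}"})
    return pd.DataFrame(rows)


def variability_filter(
    genes: list,
    expr: pd.DataFrame,
    cohorts: pd.Series,
    max_logfc: float = 3.0,
) -> pd.DataFrame:
    """Drop genes whose cohort mean logCPM differs by more than
    ``max_logfc`` between any two cohorts."""
    if cohorts.nunique() < 2:
        raise ValueError("variability filter needs >= 2 cohorts")
    samples = expr.columns.intersection(cohorts.index)
    rows = []
    for g in genes:
        means = expr.loc[g, samples].groupby(cohorts.loc[samples]).mean()
        spread = float(means.max() - means.min())
        rows.append({"gene_id": g, "max_cohort_logfc": spread, "kept": spread <= max_logfc})
    return pd.DataFrame(rows)


@dataclass
class RiskModel:
    """Trained ensemble plus everything needed to score new samples."""

    genes: list
    forest: RandomForestClassifier
    threshold: float = 0.7
    train_means: pd.Series | None = None  # per-gene means for imputation
    version: str = "1"

    def k_scores(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting the relapse (positive) class."""
        pos = list(self.forest.classes_).index(1)
        votes = np.stack([t.predict(X) == self.forest.classes_[pos] for t in self.forest.estimators_])
        return votes.mean(axis=0)


def _make_forest(n_trees: int, mtry: int, seed: int) -> RandomForestClassifier:
    # balanced class weights neutralize the class-prior shift a held-out
    # sample induces in its leave-one-out training fold, keeping vote
    # fractions comparable across folds
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features=mtry,
        bootstrap=True,
        class_weight="balanced",
        random_state=seed,
        n_jobs=1,
    )


def train_model(
    expr: pd.DataFrame,
    labels: pd.Series,
    n_trees: int = 400,
    mtry: int = 4,
    threshold: float = 0.7,
    seed: int = 0,
) -> RiskModel:
    """Single model on all provided samples (rows of ``expr`` = genes)."""
    samples = expr.columns.intersection(labels.dropna().index)
    y = labels.loc[samples].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    X = expr[samples].to_numpy().T
    forest = _make_forest(n_trees, min(mtry, expr.shape[0]), seed)
    forest.fit(X, y)
    return RiskModel(
        genes=list(expr.index),
        forest=forest,
        threshold=threshold,
        train_means=expr[samples].mean(axis=1),
    )


def train_and_score_loo(
    expr: pd.DataFrame,
    labels: pd.Series,
    n_trees: int = 400,
    mtry: int = 4,
    threshold: float = 0.7,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-out k-scores: per held-out sample, an ensemble trained on
    the rest votes; feature selection is fixed upstream."""
    samples = list(expr.columns.intersection(labels.dropna().index))
    if len(samples) < 20:
        raise ValueError("leave-one-out evaluation needs n >= 20")
    y = labels.loc[samples].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    X = expr[samples].to_numpy().T
    scores = np.empty(len(samples))
    mtry_eff = min(mtry, expr.shape[0])
    for i in range(len(samples)):
        mask = np.ones(len(samples), dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            raise ValueError("single-class training fold")
        forest = _make_forest(n_trees, mtry_eff, seed)
        forest.fit(X[mask], y[mask])
        pos = list(forest.classes_).index(1)
        votes = np.stack([t.predict(X[i : i + 1]) == forest.classes_[pos] for t in forest.estimators_])
        scores[i] = votes.mean()
    out = pd.DataFrame(
        {"sample_id": samples, "k_score": scores, "label": y}
    ).set_index("sample_id")
    out["risk_class"] = np.where(out.k_score >= threshold, "high", "low")
    return out


def apply_model(model: RiskModel, expr: pd.DataFrame) -> pd.DataFrame:
    """Score new samples; tolerates <= 10% missing signature genes by
    mean imputation (training means), errors beyond that."""
    if expr.shape[1] == 0:
        raise ValueError("empty expression matrix")
    missing = [g for g in model.genes if g not in expr.index]
    if len(missing) > 0.10 * len(model.genes):
        raise ValueError(
            f"{len(missing)}/{len(model.genes)} signature genes missing (> 10%): {missing[:5]}"
        )
    rows = []
    for g in model.genes:
        if g in expr.index:
            rows.append(expr.loc[g].to_numpy(dtype=float))
        else:
            warnings.warn(f"signature gene {g} missing; mean-imputed")
            fill = float(model.train_means[g]) if model.train_means is not None else 0.0
            rows.append(np.full(expr.shape[1], fill))
    X = np.vstack(rows).T
    k = model.k_scores(X)
    out = pd.DataFrame({"sample_id": expr.columns, "k_score": k}).set_index("sample_id")
    out["risk_class"] = np.where(out.k_score >= model.threshold, "high", "low")
    if missing:
        out.attrs["missing_genes"] = missing
    return out


def evaluate(
    scores: pd.Series,
    labels: pd.Series,
    times: pd.Series | None = None,
    events: pd.Series | None = None,
    threshold: float = 0.7,
) -> dict:
    """ROC/AUC of the k-score plus KM curves and log-rank at the split.

    AUC is the rank statistic (ties averaged). When one risk class is
    empty after thresholding, KM/log-rank are skipped with a warning but
    the ROC is still computed.
    """
    samples = scores.index.intersection(labels.dropna().index)
    y = labels.loc[samples].astype(int).to_numpy()
    s = scores.loc[samples].to_numpy(dtype=float)
    fpr, tpr, thr = roc_curve(y, s)
    out = {
        "auc": float(roc_auc_score(y, s)),
        "roc": pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        "km": None,
        "logrank_stat": None,
        "logrank_p": None,
    }
    if times is None or events is None:
        return out
    high = s >= threshold
    if high.all() or (~high).all():
        warnings.warn("one risk class empty at the threshold; KM/log-rank skipped")
        return out
    t = times.loc[samples].to_numpy(dtype=float)
    e = events.loc[samples].astype(int).to_numpy()
    km = {}
    for name, mask in (("high", high), ("low", ~high)):
        f = KaplanMeierFitter()
        f.fit(t[mask], e[mask], label=name)
        km[name] = f.survival_function_
    lr = logrank_test(t[high], t[~high], e[high], e[~high])
    out["km"] = km
    out["logrank_stat"] = float(lr.test_statistic)
    out["logrank_p"] = float(lr.p_value)
    return out


def threshold_sweep(scores: pd.Series, labels: pd.Series, grid=None) -> pd.DataFrame:
    """Sensitivity/specificity/accuracy over the threshold range."""
    if grid is None:
        grid = np.round(np.arange(0.05, 1.0, 0.05), 2)
    samples = scores.index.intersection(labels.dropna().index)
    y = labels.loc[samples].astype(int).to_numpy()
    s = scores.loc[samples].to_numpy(dtype=float)
    rows = []
    for th in grid:
        pred = (s >= th).astype(int)
        tp = int(((pred == 1) & (y == 1)).sum())
        tn = int(((pred == 0) & (y == 0)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        rows.append(
            {
                "threshold": th,
                "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
                "specificity": tn / (tn + fp) if tn + fp else np.nan,
                "accuracy": (tp + tn) / len(y),
            }
        )
    return pd.DataFrame(rows)
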