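"""Shared statistical primitives used across the pipeline.

Benjamini-Hochberg correction, the covariate-adjusted per-feature linear
model (used for both differential expression on logCPM and differential
splicing on logit PSI), and empirical-Bayes variance moderation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats, optimize
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "logit",
    "inv_logit",
    "build_design",
    "fit_feature_lm",
    "moderate_variances",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    Single repo-wide implementation; NaN p-values propagate as NaN and do
    not count toward the number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def logit(x, eps: float = 0.01) -> np.ndarray:
    """Logit with clipping to [eps, 1-eps] so boundary proportions stay finite."""
    x = np.clip(np.asarray(x, dtype=float), eps, 1.0 - eps)
    return np.log(x / (1.0 - x))


def inv_logit(y) -> np.ndarray:
    return special.expit(np.asarray(y, dtype=float))


def build_design(groups: pd.Series, covariates: pd.DataFrame | None) -> tuple[np.ndarray, list[str]]:
    """Design matrix [intercept, group, covariate dummies].

    ``groups`` must be binary-codable (two levels); the second sorted level
    is coded 1 so the group coefficient is "level2 minus level1".
    Categorical covariates are dummy-coded dropping the first level.
    Raises ValueError when the group indicator is collinear with the
    covariates (confounded design).
    """
    levels = sorted(pd.unique(groups.dropna()))
    if len(levels) != 2:
        raise ValueError(f"expected exactly two group levels, got {levels}")
    g = (groups == levels[1]).astype(float).to_numpy()
    cols = [np.ones_like(g), g]
    names = ["intercept", f"{levels[1]}_vs_{levels[0]}"]
    if covariates is not None and covariates.shape[1]:
        dummies = pd.get_dummies(covariates, drop_first=True, dtype=float)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy())
            names.append(str(c))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "design matrix is rank-deficient: the group factor is aliased "
            "with a covariate (confounded design)"
        )
    return X, names


def moderate_variances(s2: np.ndarray, df_resid: int) -> tuple[np.ndarray, float, float, float]:
    """Empirical-Bayes squeeze of per-feature residual variances.

    Method-of-moments fit of a scaled inverse chi-square prior on the
    distribution of log sample variances: with d residual df,
    Var(log s^2) = trigamma(d/2) + trigamma(d0/2), so d0 is recovered by
    inverting the trigamma function and s0^2 from the mean of log s^2.
    Returns (posterior variances, d0, s0sq, total df).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    z = np.log(s2[ok])
    d = float(df_resid)
    e_z = z.mean() - special.polygamma(0, d / 2) + np.log(d / 2)
    var_z = z.var(ddof=1) - special.polygamma(1, d / 2)
    if var_z <= 0:
        # sample variances less dispersed than chi-square sampling noise:
        # infinite prior df, all variances shrunk to the common value
        d0 = np.inf
        s0sq = float(np.exp(e_z))
        post = np.full_like(s2, s0sq)
        return post, d0, s0sq, np.inf

    def f(x):
        return special.polygamma(1, x / 2) - var_z

    d0 = optimize.brentq(f, 1e-6, 1e7)
    s0sq = float(np.exp(e_z + special.polygamma(0, d0 / 2) - np.log(d0 / 2)))
    post = (d0 * s0sq + d * s2) / (d0 + d)
    return post, d0, s0sq, d0 + d


def fit_feature_lm(
    Y: np.ndarray,
    X: np.ndarray,
    coef_index: int = 1,
    moderate: bool = True,
) -> pd.DataFrame:
    """Ordinary least squares of every row of Y on X, t-test on one coefficient.

    Vectorized across features (rows of Y). Returns a DataFrame with
    columns coef, se, t, p, df. With ``moderate`` the residual variances
    are squeezed toward a common prior before forming the t-statistics.
    """
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    k = X.shape[1]
    df_resid = n - k
    if df_resid < 1:
        raise ValueError("not enough residual degrees of freedom")
    XtX_inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ XtX_inv.T  # features x k
    resid = Y - B @ X.T
    s2 = (resid**2).sum(axis=1) / df_resid
    c = XtX_inv[coef_index, coef_index]
    if moderate and Y.shape[0] >= 10:
        s2_post, _, _, df_total = moderate_variances(s2, df_resid)
    else:
        s2_post, df_total = s2, float(df_resid)
    se = np.sqrt(np.maximum(s2_post * c, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = B[:, coef_index] / se
    df_t = df_total if np.isfinite(df_total) else 1e9
    p = 2.0 * stats.t.sf(np.abs(t), df_t)
    return pd.DataFrame(
        {"coef": B[:, coef_index], "se": se, "t": t, "p": p, "df": df_t}
    )
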