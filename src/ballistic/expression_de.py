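"""Transcript TPM to gene counts, TMM normalization, covariate-adjusted
differential expression and pre-ranked gene-set enrichment.

Gene counts are reconstructed from transcript TPM by length-weighting
(pseudo-count = TPM x length, rescaled so each sample's counts sum to its
library size), the standard abundance-to-counts conversion. Library
normalization uses trimmed-mean-of-M-values (TMM) factors; expression is
modelled on log2 counts per million (logCPM, prior count 0.5) with a
per-gene linear model on group + sex + project + tissue and optional
empirical-Bayes variance moderation. Genes are ranked by
r = -log10(p) * log2FC for a weighted Kolmogorov-Smirnov pre-ranked
enrichment test with gene-label permutations.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from ._stats import bh_adjust, build_design, fit_feature_lm

__all__ = [
    "tpm_to_gene_counts",
    "tmm_normalize",
    "logcpm",
    "fit_de",
    "preranked_gsea",
    "enrichment_score",
    "read_gmt",
]


def tpm_to_gene_counts(
    tpm: pd.DataFrame,
    transcript_lengths: pd.Series,
    transcript_gene: pd.Series,
    library_sizes: pd.Series,
) -> pd.DataFrame:
    """Gene-level counts from transcript TPM.

    Per sample: pseudo-count_t = TPM_t * length_t * (libsize / sum_t TPM_t * length_t);
    gene count = sum over its transcripts. Column sums equal the library sizes.
    """
    unknown = [t for t in tpm.index if t not in transcript_gene.index]
    if unknown:
        raise ValueError(f"unknown transcript id(s): {unknown[:5]}")
    lens = transcript_lengths.loc[tpm.index].to_numpy(dtype=float)
    if (lens <= 0).any():
        raise ValueError("non-positive transcript length")
    pseudo = tpm.to_numpy(dtype=float) * lens[:, None]
    denom = pseudo.sum(axis=0)
    libs = library_sizes.loc[tpm.columns].to_numpy(dtype=float)
    counts = pseudo * (libs / denom)[None, :]
    df = pd.DataFrame(counts, index=tpm.index, columns=tpm.columns)
    return df.groupby(transcript_gene.loc[tpm.index].to_numpy()).sum()


def tmm_normalize(
    counts: pd.DataFrame,
    library_sizes: pd.Series | None = None,
    logratio_trim: float = 0.30,
    abs_expr_trim: float = 0.05,
) -> pd.Series:
    """TMM normalization factors, rescaled to geometric mean 1.

    Reference sample: upper-quartile (of count/libsize over positive
    counts) closest to the mean upper-quartile. Per sample, the factor is
    2 to the precision-weighted mean of M-values after trimming
    ``logratio_trim`` from each tail of M and ``abs_expr_trim`` from each
    tail of A.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    X = counts.to_numpy(dtype=float)
    zero_cols = X.sum(axis=0) == 0
    if zero_cols.any():
        raise ValueError(f"all-zero sample(s): {list(counts.columns[zero_cols])}")
    if library_sizes is None:
        libs = X.sum(axis=0)
    else:
        libs = library_sizes.loc[counts.columns].to_numpy(dtype=float)

    def uq(j):
        col = X[:, j]
        pos = col[col > 0]
        return np.quantile(pos / libs[j], 0.75)

    uqs = np.array([uq(j) for j in range(X.shape[1])])
    ref = int(np.argmin(np.abs(uqs - uqs.mean())))

    log_factors = np.zeros(X.shape[1])
    xr, nr = X[:, ref], libs[ref]
    for j in range(X.shape[1]):
        if j == ref:
            continue
        x, n = X[:, j], libs[j]
        ok = (x > 0) & (xr > 0)
        m = np.log2((x[ok] / n) / (xr[ok] / nr))
        a = 0.5 * np.log2((x[ok] / n) * (xr[ok] / nr))
        w = (n - x[ok]) / (n * x[ok]) + (nr - xr[ok]) / (nr * xr[ok])
        if np.allclose(m.max(initial=0) - m.min(initial=0), 0):
            continue
        nkeep = m.size
        m_rank = pd.Series(m).rank(method="first").to_numpy()
        a_rank = pd.Series(a).rank(method="first").to_numpy()
        lo_m = np.floor(nkeep * logratio_trim) + 1
        hi_m = nkeep + 1 - lo_m
        lo_a = np.floor(nkeep * abs_expr_trim) + 1
        hi_a = nkeep + 1 - lo_a
        keep = (m_rank >= lo_m) & (m_rank <= hi_m) & (a_rank >= lo_a) & (a_rank <= hi_a)
        if keep.sum() == 0:
            continue
        log_factors[j] = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    factors = np.power(2.0, log_factors)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def logcpm(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    library_sizes: pd.Series | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """log2 counts per million on TMM-scaled library sizes."""
    libs = (
        counts.sum(axis=0)
        if library_sizes is None
        else library_sizes.loc[counts.columns].astype(float)
    )
    if factors is not None:
        libs = libs * factors.loc[counts.columns]
    return np.log2((counts + prior_count).div(libs + 1.0, axis=1) * 1e6)


def fit_de(
    expr: pd.DataFrame,
    groups: pd.Series,
    covariates: pd.DataFrame | None = None,
    moderate: bool = True,
    min_mean: float = 0.0,
    fdr_max: float = 0.01,
    lfc_min: float = 1.0,
) -> pd.DataFrame:
    """Per-gene differential expression on logCPM.

    Genes with mean logCPM below ``min_mean`` are filtered out before
    fitting. Returns log2FC (group coefficient), p, BH FDR, the rank
    metric r = -log10(p) * log2FC and a significance flag at
    FDR < ``fdr_max`` and |log2FC| > ``lfc_min``.
    """
    samples = groups.dropna().index.intersection(expr.columns)
    groups = groups.loc[samples]
    for lvl, cnt in groups.value_counts().items():
        if cnt == 0:
            raise ValueError(f"empty contrast group {lvl}")
    expr = expr[samples]
    kept = expr.loc[expr.mean(axis=1) >= min_mean]
    X, names = build_design(groups, covariates.loc[samples] if covariates is not None else None)
    fit = fit_feature_lm(kept.to_numpy(), X, coef_index=1, moderate=moderate)
    out = pd.DataFrame(
        {
            "gene_id": kept.index,
            "log2fc": fit.coef.to_numpy(),
            "mean_logcpm": kept.mean(axis=1).to_numpy(),
            "p": fit.p.to_numpy(),
        }
    )
    out["fdr"] = bh_adjust(out.p)
    with np.errstate(divide="ignore"):
        out["rank_metric"] = -np.log10(np.maximum(out.p, 1e-300)) * out.log2fc
    out["significant"] = (out.fdr < fdr_max) & (out.log2fc.abs() > lfc_min)
    out.attrs["contrast"] = names[1]
    return out


# ----------------------------------------------------------------------- GSEA


def enrichment_score(metric: pd.Series, gene_set: set, weight: float = 1.0) -> float:
    """Weighted Kolmogorov-Smirnov enrichment score.

    Genes sorted by decreasing metric; hits increment proportionally to
    |r|^weight (uniformly when weight = 0), misses decrement uniformly;
    ES is the signed extremum of the running sum.
    """
    order = metric.sort_values(ascending=False, kind="mergesort")
    in_set = order.index.isin(gene_set)
    n, k = len(order), int(in_set.sum())
    if k == 0 or k == n:
        return 0.0
    w = np.abs(order.to_numpy()) ** weight
    hit_w = np.where(in_set, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all set genes have zero metric
        hit_w = in_set.astype(float)
        denom = float(k)
    steps = hit_w / denom - (~in_set) / (n - k)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def preranked_gsea(
    metric: pd.Series,
    gene_sets: dict,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
    absolute: bool = False,
) -> pd.DataFrame:
    """Pre-ranked GSEA with a gene-label permutation null.

    ``absolute`` ranks genes by |r| (used for the splicing-factor/RBP
    list, which has no signed direction). NES = ES divided by the mean
    |null ES| of the same sign; p and FDR come from the same-sign pooled
    null distribution.
    """
    metric = metric.dropna()
    if not np.isfinite(metric).all():
        raise ValueError("rank metric contains non-finite values")
    if absolute:
        metric = metric.abs()
    rng = np.random.default_rng(seed)
    genes = np.array(metric.index)
    rows = []
    null_pool: dict[str, np.ndarray] = {}
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & set(genes)
        if not members:
            warnings.warn(f"gene set {name} empty after intersection; skipped")
            continue
        es = enrichment_score(metric, members, weight)
        null = np.empty(n_perm)
        k = len(members)
        for b in range(n_perm):
            fake = set(rng.choice(genes, size=k, replace=False))
            null[b] = enrichment_score(metric, fake, weight)
        null_pool[name] = null
        same = null[null * np.sign(es) >= 0] if es != 0 else null
        denom = np.abs(same).mean() if same.size else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else 0.0
        p = ((np.abs(same) >= abs(es)).sum() + 1) / (same.size + 1) if same.size else 1.0
        rows.append({"set": name, "size": k, "es": es, "nes": nes, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out.p)
    return out


def read_gmt(path: str | Path) -> dict:
    sets = {}
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) >= 3:
            sets[parts[0]] = parts[2:]
    return sets
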