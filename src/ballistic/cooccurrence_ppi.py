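"""Probabilistic co-occurrence testing and PPI-based interactor reports.

The co-occurrence model conditions on the two marginal presence counts
(m_A, m_B) over N samples and treats all placements as equally likely, so
the co-occurrence count j follows the hypergeometric distribution

    P(j) = C(m_A, j) C(N - m_A, m_B - j) / C(N, m_B).

``p_lt`` = P(j_obs or fewer co-occurrences) and ``p_gt`` = P(j_obs or
more); a pair is called negatively associated (mutually exclusive) when
p_lt < alpha and positively associated when p_gt < alpha.

The same test drives (a) mutual-exclusivity grouping of fusion groups,
and (b) the association of binarized splicing-event inclusion with the
high-risk label within each fusion group. PPI edges in STRING-style
tables are filtered at experimental > 0 and combined > 900.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

__all__ = [
    "CooccurResult",
    "cooccur_test",
    "event_risk_cooccurrence",
    "filter_ppi",
    "interactor_overlap",
]


@dataclass
class CooccurResult:
    n: int
    m_a: int
    m_b: int
    observed: int
    expected: float
    p_lt: float  # P(co-occurrence count <= observed)
    p_gt: float  # P(co-occurrence count >= observed)

    @property
    def call(self) -> str:
        if self.p_gt < 0.05:
            return "positive"
        if self.p_lt < 0.05:
            return "negative"
        return "random"


def cooccur_test(a, b, expected_min: float | None = None) -> CooccurResult:
    """Exact co-occurrence test of two binary vectors with fixed marginals.

    ``expected_min``: when set (the original species-co-occurrence
    package uses 1), pairs with expected co-occurrence below it raise a
    ValueError; off by default.
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D binary vectors")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("inputs must be binary")
    n = a.size
    m_a, m_b = int(a.sum()), int(b.sum())
    if m_a > n or m_b > n:
        raise ValueError("marginal exceeds the number of samples")
    j = int((a & b).sum())
    expected = m_a * m_b / n if n else 0.0
    if expected_min is not None and expected < expected_min:
        raise ValueError(f"expected co-occurrence {expected:.3g} < {expected_min}")
    # hypergeometric: j successes drawing m_b from m_a marked among n
    dist = stats.hypergeom(n, m_a, m_b)
    p_lt = float(dist.cdf(j))
    p_gt = float(dist.sf(j - 1))
    return CooccurResult(n=n, m_a=m_a, m_b=m_b, observed=j, expected=expected, p_lt=min(p_lt, 1.0), p_gt=min(p_gt, 1.0))


def event_risk_cooccurrence(
    event_matrix: pd.DataFrame,
    risk_high: pd.Series,
    groups: pd.Series,
    alpha: float = 0.05,
    min_samples: int = 5,
) -> pd.DataFrame:
    """Test event-inclusion / high-risk co-occurrence within fusion groups.

    ``event_matrix``: events x samples binary; ``risk_high``: per-sample
    0/1 high-risk indicator; ``groups``: per-sample fusion-group label.
    BH correction is applied across events within each group. Groups with
    fewer than ``min_samples`` samples or without both risk classes are
    skipped with a warning.
    """
    rows = []
    for g in sorted(groups.dropna().unique()):
        samples = groups.index[groups == g]
        samples = [s for s in samples if s in event_matrix.columns and s in risk_high.index]
        if len(samples) < min_samples:
            warnings.warn(f"fusion group {g}: fewer than {min_samples} samples; skipped")
            continue
        risk = risk_high.loc[samples].to_numpy().astype(int)
        if risk.min() == risk.max():
            warnings.warn(f"fusion group {g}: no risk contrast; skipped")
            continue
        sub = event_matrix[samples]
        res = []
        for ev in sub.index:
            r = cooccur_test(sub.loc[ev].to_numpy().astype(int), risk)
            res.append((ev, r.observed, r.expected, r.p_gt, r.p_lt))
        df = pd.DataFrame(res, columns=["event_id", "observed", "expected", "p_gt", "p_lt"])
        df["group"] = g
        df["fdr_gt"] = bh_adjust(df.p_gt)
        df["significant"] = df.fdr_gt < alpha
        rows.append(df)
    if not rows:
        return pd.DataFrame(
            columns=["event_id", "observed", "expected", "p_gt", "p_lt", "group", "fdr_gt", "significant", "n_groups_significant"]
        )
    out = pd.concat(rows, ignore_index=True)
    rec = out[out.significant].groupby("event_id").size()
    out["n_groups_significant"] = out.event_id.map(rec).fillna(0).astype(int)
    return out


def filter_ppi(edges: pd.DataFrame) -> pd.DataFrame:
    """Keep STRING-style edges with experimental > 0 and combined > 900."""
    for col in ("experimental", "combined"):
        if col not in edges.columns:
            raise ValueError(f"missing column {col}")
        vals = edges[col].astype(float)
        if ((vals < 0) | (vals > 1000)).any():
            bad = edges.index[(vals < 0) | (vals > 1000)][0]
            raise ValueError(f"score out of range [0, 1000] at row {bad}")
    keep = (edges.experimental > 0) & (edges.combined > 900)
    return edges.loc[keep].reset_index(drop=True)


def interactor_overlap(
    enriched_rbps: list[str],
    signature_genes: list[str],
    hub_gene: str,
    ppi: pd.DataFrame,
) -> pd.DataFrame:
    """Per enriched-motif RBP: interaction with the hub and the signature.

    ``ppi`` must already be filtered. Returns one row per RBP with its
    hub-neighbor status, the signature genes it touches, and whether the
    RBP is itself a signature member.
    """
    if not len(enriched_rbps) or not len(signature_genes):
        raise ValueError("enriched RBP list and signature must be non-empty")
    neighbors: dict[str, set] = {}
    for a, b in zip(ppi.protein_a, ppi.protein_b):
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)
    if hub_gene not in neighbors:
        warnings.warn(f"hub gene {hub_gene} absent from the PPI graph")
    sig = set(signature_genes)
    rows = []
    for rbp in sorted(set(enriched_rbps)):
        nb = neighbors.get(rbp, set())
        rows.append(
            {
                "rbp": rbp,
                "interacts_hub": hub_gene in nb,
                "signature_interactors": ",".join(sorted(nb & sig)),
                "n_signature_interactors": len(nb & sig),
                "is_signature_member": rbp in sig,
            }
        )
    return pd.DataFrame(rows)
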