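"""Alternative-splicing events, PSI computation and differential splicing.

Events of the seven standard types (SE, A3, A5, AF, AL, MX, RI) are
enumerated from annotation by pairwise transcript comparison within each
gene, using coordinate signatures so duplicates collapse. PSI per event
and sample is the TPM of the inclusion transcripts over the TPM of all
transcripts involved in the event, undefined below 1 TPM total. Events
missing in more than 10% of samples are discarded; remaining holes are
filled by k-nearest-neighbour averaging over events. Differential
inclusion between two sample groups uses a linear model on
logit-transformed PSI with the same covariate adjustment as the
expression analysis; significance requires |dPSI| > 0.2 and FDR < 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from ._stats import bh_adjust, build_design, fit_feature_lm, logit
from .annotation import AnnotationBundle, Transcript

__all__ = [
    "SplicingEvent",
    "generate_events",
    "se_event_id",
    "compute_psi",
    "filter_and_impute",
    "diff_splice",
    "binarize_inclusion",
    "psi_expression_correlation",
    "events_to_frame",
]

EVENT_TYPES = ("SE", "A3", "A5", "AF", "AL", "MX", "RI")


@dataclass(frozen=True)
class SplicingEvent:
    event_id: str
    gene_id: str
    etype: str
    chrom: str
    strand: str
    inclusion_transcripts: tuple
    total_transcripts: tuple
    span: tuple  # genomic (start, end) of the variable region
    sites: tuple  # alternative splice-site positions (genomic, 1-based)
    coding: bool = False


def se_event_id(gene_id, chrom, a_end, c_start, c_end, b_start, strand) -> str:
    """Signature of a cassette (skipped) exon event."""
    return f"{gene_id};SE:{chrom}:{a_end}-{c_start}:{c_end}-{b_start}:{strand}"


def _junctions(t: Transcript) -> list[tuple[int, int]]:
    ex = t.exons
    return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)]


def _has_junction(t: Transcript, j: tuple[int, int]) -> bool:
    return j in set(_junctions(t))


def generate_events(bundle: AnnotationBundle) -> list[SplicingEvent]:
    """Enumerate the 7 event types by pairwise transcript comparison.

    Deduplicated by coordinate signature; membership (inclusion vs total
    transcript sets) is recomputed against every transcript of the gene
    so events shared by more than two isoforms get complete sets.
    Transcript input order does not affect the result.
    """
    events: dict[str, SplicingEvent] = {}
    for gid in sorted(bundle.genes.index):
        txs = sorted(bundle.transcripts_of(gid), key=lambda t: t.transcript_id)
        if len(txs) < 2:
            continue
        chrom = bundle.chrom(gid)
        strand = bundle.strand(gid)
        try:
            for t in txs:  # malformed structures may bypass construction checks
                for (a, b), (c, d) in zip(t.exons, t.exons[1:]):
                    if c <= b:
                        raise ValueError(
                            f"{t.transcript_id}: overlapping exons ({a},{b}) and ({c},{d})"
                        )
            found: list[tuple] = []
            for i in range(len(txs)):
                for j in range(i + 1, len(txs)):
                    found.extend(_pair_events(txs[i], txs[j], strand))
        except ValueError as exc:  # malformed transcript structures
            warnings.warn(f"gene {gid} skipped: {exc}")
            continue
        for etype, sig_coords, inc_test, exc_test, span, sites in found:
            eid = f"{gid};{etype}:{chrom}:{sig_coords}:{strand}"
            if eid in events:
                continue
            inc = tuple(t.transcript_id for t in txs if inc_test(t))
            exc = tuple(t.transcript_id for t in txs if exc_test(t))
            if not inc or not exc:
                continue
            total = tuple(sorted(set(inc) | set(exc)))
            coding = any(
                bundle.transcripts[t].cds_start is not None
                and bundle.transcripts[t].cds_start <= span[1]
                and bundle.transcripts[t].cds_end >= span[0]
                for t in total
            )
            events[eid] = SplicingEvent(
                event_id=eid,
                gene_id=gid,
                etype=etype,
                chrom=chrom,
                strand=strand,
                inclusion_transcripts=tuple(sorted(inc)),
                total_transcripts=total,
                span=span,
                sites=sites,
                coding=coding,
            )
    return [events[k] for k in sorted(events)]


def _pair_events(t1: Transcript, t2: Transcript, strand: str) -> list[tuple]:
    """Local event patterns between two transcripts.

    Each item: (etype, signature-coords, inclusion-membership-test,
    exclusion-membership-test, variable-region span, splice sites).
    """
    out: list[tuple] = []
    for t_inc, t_exc in ((t1, t2), (t2, t1)):
        ex_i, ex_e = t_inc.exons, t_exc.exons
        jset_e = set(_junctions(t_exc))
        # --- SE: cassette exon C flanked by shared boundaries
        for k in range(1, len(ex_i) - 1):
            a_end = ex_i[k - 1][1]
            c = ex_i[k]
            b_start = ex_i[k + 1][0]
            if (a_end, b_start) in jset_e:
                def inc_test(t, a_end=a_end, c=c, b_start=b_start):
                    return _has_junction(t, (a_end, c[0])) and _has_junction(t, (c[1], b_start))

                def exc_test(t, a_end=a_end, b_start=b_start):
                    return _has_junction(t, (a_end, b_start))

                out.append(
                    (
                        "SE",
                        f"{a_end}-{c[0]}:{c[1]}-{b_start}",
                        inc_test,
                        exc_test,
                        (c[0], c[1]),
                        (a_end, c[0], c[1], b_start),
                    )
                )
        # --- RI: single exon in t_inc spanning two exons + intron of t_exc
        for a, d in ex_i:
            for k in range(len(ex_e) - 1):
                (xa, xb), (xc, xd) = ex_e[k], ex_e[k + 1]
                if xa == a and xd == d and xb < xc:
                    def ri_inc(t, a=a, d=d):
                        return any(e == (a, d) for e in t.exons)

                    def ri_exc(t, xb=xb, xc=xc):
                        return _has_junction(t, (xb, xc))

                    out.append(
                        (
                            "RI",
                            f"{a}:{xb}-{xc}:{d}",
                            ri_inc,
                            ri_exc,
                            (xb + 1, xc - 1),
                            (xb, xc),
                        )
                    )
    # symmetric (unordered) patterns once
    j1, j2 = set(_junctions(t1)), set(_junctions(t2))
    acc1 = {a: (a, b) for a, b in t1.exons}  # exon by start
    acc2 = {a: (a, b) for a, b in t2.exons}
    don1 = {b: (a, b) for a, b in t1.exons}  # exon by end
    don2 = {b: (a, b) for a, b in t2.exons}
    # --- A3/A5: shared donor, alternative acceptors of overlapping exons
    for d in {a for a, _ in j1} & {a for a, _ in j2}:
        s1s = sorted(b for a, b in j1 if a == d)
        s2s = sorted(b for a, b in j2 if a == d)
        for s1 in s1s:
            for s2 in s2s:
                if s1 == s2:
                    continue
                (lo, lo_exon), (hi, hi_exon) = sorted(
                    ((s1, acc1[s1]), (s2, acc2[s2]))
                )
                if lo_exon[1] < hi:  # acceptor exons must overlap
                    continue
                etype = "A3" if strand == "+" else "A5"

                def a_inc(t, d=d, lo=lo):
                    return _has_junction(t, (d, lo))

                def a_exc(t, d=d, hi=hi):
                    return _has_junction(t, (d, hi))

                out.append(
                    (etype, f"{d}-{lo}:{d}-{hi}", a_inc, a_exc, (lo, hi - 1), (d, lo, hi))
                )
    # shared acceptor, alternative donors of overlapping exons
    for s in {b for _, b in j1} & {b for _, b in j2}:
        d1s = sorted(a for a, b in j1 if b == s)
        d2s = sorted(a for a, b in j2 if b == s)
        for d1 in d1s:
            for d2 in d2s:
                if d1 == d2:
                    continue
                (lo, lo_exon), (hi, hi_exon) = sorted(
                    ((d1, don1[d1]), (d2, don2[d2]))
                )
                if hi_exon[0] > lo:  # donor exons must overlap
                    continue
                etype = "A5" if strand == "+" else "A3"

                def a5_inc(t, s=s, hi=hi):
                    return _has_junction(t, (hi, s))

                def a5_exc(t, s=s, lo=lo):
                    return _has_junction(t, (lo, s))

                out.append(
                    (etype, f"{lo}-{s}:{hi}-{s}", a5_inc, a5_exc, (lo + 1, hi), (s, lo, hi))
                )
    # --- MX: mutually exclusive exons between shared flanks
    for ta, tb in ((t1, t2),):
        for k in range(1, len(ta.exons) - 1):
            for m in range(1, len(tb.exons) - 1):
                a_end_a, ca, b_sta_a = ta.exons[k - 1][1], ta.exons[k], ta.exons[k + 1][0]
                a_end_b, cb, b_sta_b = tb.exons[m - 1][1], tb.exons[m], tb.exons[m + 1][0]
                if a_end_a == a_end_b and b_sta_a == b_sta_b and ca != cb:
                    if ca[1] < cb[0] or cb[1] < ca[0]:  # non-overlapping
                        c1, c2 = sorted((ca, cb))

                        def mx_inc(t, a=a_end_a, c=c1, b=b_sta_a):
                            return _has_junction(t, (a, c[0])) and _has_junction(t, (c[1], b))

                        def mx_exc(t, a=a_end_a, c=c2, b=b_sta_a):
                            return _has_junction(t, (a, c[0])) and _has_junction(t, (c[1], b))

                        out.append(
                            (
                                "MX",
                                f"{a_end_a}-{c1[0]}:{c1[1]}-{b_sta_a}:{a_end_a}-{c2[0]}:{c2[1]}-{b_sta_a}",
                                mx_inc,
                                mx_exc,
                                (c1[0], c2[1]),
                                (a_end_a, c1[0], c1[1], c2[0], c2[1], b_sta_a),
                            )
                        )
    # --- AF/AL: distinct non-overlapping terminal exons joined to a shared exon
    for which in ("first", "last"):
        if len(t1.exons) < 2 or len(t2.exons) < 2:
            continue
        if which == "first":
            f1, f2 = t1.exons[0], t2.exons[0]
            c1, c2 = t1.exons[1][0], t2.exons[1][0]
            shared = c1 == c2 and f1 != f2 and (f1[1] < f2[0] or f2[1] < f1[0])
            etype = ("AF" if strand == "+" else "AL") if shared else None
            if shared:
                lo, hi = sorted((f1, f2))

                def t_inc(t, e=lo, c=c1):
                    return t.exons[0] == e and _has_junction(t, (e[1], c))

                def t_exc(t, e=hi, c=c1):
                    return t.exons[0] == e and _has_junction(t, (e[1], c))

                out.append(
                    (
                        etype,
                        f"{lo[0]}:{lo[1]}-{c1}:{hi[0]}:{hi[1]}-{c1}",
                        t_inc,
                        t_exc,
                        (lo[0], hi[1]),
                        (lo[1], hi[1], c1),
                    )
                )
        else:
            l1, l2 = t1.exons[-1], t2.exons[-1]
            c1, c2 = t1.exons[-2][1], t2.exons[-2][1]
            shared = c1 == c2 and l1 != l2 and (l1[1] < l2[0] or l2[1] < l1[0])
            if shared:
                etype = "AL" if strand == "+" else "AF"
                lo, hi = sorted((l1, l2))

                def t_inc2(t, e=lo, c=c1):
                    return t.exons[-1] == e and _has_junction(t, (c, e[0]))

                def t_exc2(t, e=hi, c=c1):
                    return t.exons[-1] == e and _has_junction(t, (c, e[0]))

                out.append(
                    (
                        etype,
                        f"{c1}-{lo[0]}:{lo[1]}:{c1}-{hi[0]}:{hi[1]}",
                        t_inc2,
                        t_exc2,
                        (lo[0], hi[1]),
                        (c1, lo[0], hi[0]),
                    )
                )
    return out


def events_to_frame(events: list[SplicingEvent]) -> pd.DataFrame:
    """ioe-style event catalog."""
    return pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "gene_id": [e.gene_id for e in events],
            "event_type": [e.etype for e in events],
            "inclusion_transcripts": [",".join(e.inclusion_transcripts) for e in events],
            "total_transcripts": [",".join(e.total_transcripts) for e in events],
            "coding": [e.coding for e in events],
        }
    )


# ------------------------------------------------------------------------ PSI


def compute_psi(
    events: list[SplicingEvent], tpm: pd.DataFrame, min_total_tpm: float = 1.0
) -> pd.DataFrame:
    """Events x samples PSI; NaN where total event TPM < ``min_total_tpm``."""
    rows = {}
    for ev in events:
        missing = [t for t in ev.total_transcripts if t not in tpm.index]
        if missing:
            raise ValueError(f"{ev.event_id}: transcripts absent from TPM matrix: {missing}")
        inc = tpm.loc[list(ev.inclusion_transcripts)].sum(axis=0)
        tot = tpm.loc[list(ev.total_transcripts)].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            psi = inc / tot
        psi[tot < min_total_tpm] = np.nan
        rows[ev.event_id] = psi
    out = pd.DataFrame(rows).T
    out.columns = tpm.columns
    return out


def filter_and_impute(
    psi: pd.DataFrame, max_missing: float = 0.10, k: int = 10
) -> pd.DataFrame:
    """Drop events missing in more than ``max_missing`` of samples; impute
    the rest by k-nearest-neighbour averaging over events (rows)."""
    if k >= psi.shape[0]:
        raise ValueError(f"k={k} must be smaller than the number of events ({psi.shape[0]})")
    frac = psi.isna().mean(axis=1)
    kept = psi.loc[frac <= max_missing]
    if kept.isna().to_numpy().any():
        imputer = KNNImputer(n_neighbors=k, weights="uniform")
        completed = imputer.fit_transform(kept.to_numpy())
        kept = pd.DataFrame(np.clip(completed, 0.0, 1.0), index=kept.index, columns=kept.columns)
    return kept


def diff_splice(
    psi: pd.DataFrame,
    groups: pd.Series,
    covariates: pd.DataFrame | None = None,
    sd_min: float = 0.1,
    dpsi_min: float = 0.2,
    fdr_max: float = 0.01,
    eps: float = 0.01,
) -> pd.DataFrame:
    """Differential inclusion between two groups on the completed matrix.

    Events with pooled PSI standard deviation below ``sd_min`` across the
    compared samples are removed. The model is OLS on logit-clipped PSI
    with group + covariates (no variance moderation, so with no
    covariates the test is the classical two-sample t-test). dPSI is
    reported on the natural scale as mean(level2) - mean(level1) with
    levels in sorted order.
    """
    samples = groups.dropna().index.intersection(psi.columns)
    groups = groups.loc[samples]
    psi = psi[samples]
    sd = psi.std(axis=1, ddof=1)
    kept = psi.loc[sd >= sd_min]
    X, names = build_design(groups, covariates.loc[samples] if covariates is not None else None)
    Y = logit(kept.to_numpy(), eps=eps)
    fit = fit_feature_lm(Y, X, coef_index=1, moderate=False)
    levels = sorted(pd.unique(groups))
    in2 = (groups == levels[1]).to_numpy()
    dpsi = kept.to_numpy()[:, in2].mean(axis=1) - kept.to_numpy()[:, ~in2].mean(axis=1)
    out = pd.DataFrame(
        {
            "event_id": kept.index,
            "dpsi": dpsi,
            "logit_coef": fit.coef.to_numpy(),
            "p": fit.p.to_numpy(),
        }
    )
    out["fdr"] = bh_adjust(out.p)
    out["significant"] = (np.abs(out.dpsi) > dpsi_min) & (out.fdr < fdr_max)
    out.attrs["contrast"] = f"{levels[1]}_vs_{levels[0]}"
    return out


def binarize_inclusion(psi: pd.DataFrame) -> pd.DataFrame:
    """Included (1) for PSI strictly above 0.5, absent (0) otherwise."""
    return (psi > 0.5).astype(int)


def psi_expression_correlation(
    psi: pd.DataFrame,
    logcpm: pd.DataFrame,
    event_gene: pd.Series,
    threshold: float = 0.5,
) -> tuple[pd.DataFrame, float]:
    """Pearson r between each event's PSI and its host gene logCPM.

    Zero-variance vectors yield undefined r and are excluded with a note.
    Returns the per-event table and the fraction with r > ``threshold``.
    """
    rows = []
    samples = psi.columns.intersection(logcpm.columns)
    for ev in psi.index:
        gene = event_gene.get(ev)
        if gene is None or gene not in logcpm.index:
            raise ValueError(f"host gene missing for event {ev}")
        x = psi.loc[ev, samples].to_numpy(dtype=float)
        y = logcpm.loc[gene, samples].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"event_id": ev, "gene_id": gene, "r": np.nan, "note": "zero variance"})
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"event_id": ev, "gene_id": gene, "r": r, "note": ""})
    table = pd.DataFrame(rows)
    defined = table.r.dropna()
    frac = float((defined > threshold).mean()) if len(defined) else np.nan
    return table, frac
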