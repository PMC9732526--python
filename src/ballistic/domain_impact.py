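"""Fusion breakpoints, protein-domain genomic mapping, kept/lost calls.

For every fusion partner a genomic breakpoint is derived on the gene's
representative transcript (longest annotated CDS): the caller's RNA
breakpoint is used verbatim when it falls inside an exon; otherwise the
5' partner gets the last base of its last retained exon and the 3'
partner the first base of its first retained exon, strand-aware.
Protein-domain spans (1-based inclusive amino-acid coordinates) are
mapped through the CDS onto genomic intervals and each domain is
classified kept (wholly on the retained side of the breakpoint) or lost
(any overlap with or placement on the removed side). GO-level rollups
count each domain once per GO label.

Coordinates are 1-based inclusive; BED export is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .annotation import AnnotationBundle, Transcript

logger = logging.getLogger(__name__)

__all__ = [
    "Breakpoint",
    "representative_transcript",
    "derive_breakpoint",
    "map_domain_to_genome",
    "aa_span_from_intervals",
    "classify_domain",
    "go_rollup",
    "analyze_catalog",
]


@dataclass(frozen=True)
class Breakpoint:
    gene_id: str
    role: str  # "5p" | "3p"
    chrom: str
    position: int  # 1-based genomic
    provenance: str  # "exonic" | "exon-boundary"


def representative_transcript(bundle: AnnotationBundle, gene_id: str) -> Transcript:
    """Longest-CDS transcript of the gene (ties: lexicographic id)."""
    txs = bundle.transcripts_of(gene_id)
    if not txs:
        raise ValueError(f"gene {gene_id} has no transcripts")
    with_cds = [t for t in txs if t.cds_start is not None]
    pool = with_cds or txs
    best = sorted(pool, key=lambda t: (-t.cds_length, t.transcript_id))[0]
    logger.debug("representative transcript for %s: %s", gene_id, best.transcript_id)
    return best


def derive_breakpoint(
    gene_id: str,
    caller_position: int,
    role: str,
    transcript: Transcript,
    strand: str,
    chrom: str,
) -> Breakpoint:
    """Genomic breakpoint for one fusion partner.

    role "5p": the partner contributing its transcription-upstream part;
    role "3p": the partner contributing its downstream part.
    """
    if role not in ("5p", "3p"):
        raise ValueError(f"role must be 5p or 3p, got {role}")
    span = transcript.span
    if not span[0] <= caller_position <= span[1]:
        raise ValueError(
            f"breakpoint {chrom}:{caller_position} outside gene {gene_id} span {span}"
        )
    for a, b in transcript.exons:
        if a <= caller_position <= b:
            return Breakpoint(gene_id, role, chrom, caller_position, "exonic")
    # intronic: snap to the retained exon boundary
    upstream_retained = role == "5p"
    genomic_left = upstream_retained == (strand == "+")
    if genomic_left:
        # last retained exon is the closest exon genomically left of the breakpoint
        cands = [b for a, b in transcript.exons if b < caller_position]
        pos = max(cands)
    else:
        cands = [a for a, b in transcript.exons if a > caller_position]
        pos = min(cands)
    return Breakpoint(gene_id, role, chrom, pos, "exon-boundary")


def map_domain_to_genome(
    aa_start: int, aa_end: int, transcript: Transcript, strand: str
) -> list[tuple[int, int]]:
    """Genomic interval list of an amino-acid span, walked across the CDS.

    aa span [a, b] covers CDS nucleotides [3(a-1)+1, 3b] in transcription
    order; the result is sorted genomically and its total length is
    exactly 3 x (b - a + 1).
    """
    pieces = transcript.cds_exon_pieces()
    if not pieces:
        raise ValueError(f"{transcript.transcript_id} has no CDS")
    total = sum(b - a + 1 for a, b in pieces)
    if aa_end * 3 > total:
        raise ValueError(
            f"aa span ({aa_start},{aa_end}) exceeds protein length {total // 3}"
        )
    if not 1 <= aa_start <= aa_end:
        raise ValueError("invalid aa span")
    nt_lo, nt_hi = 3 * (aa_start - 1) + 1, 3 * aa_end  # 1-based CDS coords
    walk = pieces if strand == "+" else [(b, a) for a, b in reversed(pieces)]
    out = []
    seen = 0
    for p, q in walk:
        step = 1 if q >= p else -1
        ln = abs(q - p) + 1
        lo_off = max(nt_lo, seen + 1) - (seen + 1)
        hi_off = min(nt_hi, seen + ln) - (seen + 1)
        if lo_off <= hi_off:
            g1 = p + step * lo_off
            g2 = p + step * hi_off
            out.append((min(g1, g2), max(g1, g2)))
        seen += ln
        if seen >= nt_hi:
            break
    return sorted(out)


def aa_span_from_intervals(
    intervals: list[tuple[int, int]], transcript: Transcript, strand: str
) -> tuple[int, int]:
    """Inverse of :func:`map_domain_to_genome` (exact on mapped output)."""
    pieces = transcript.cds_exon_pieces()
    walk = pieces if strand == "+" else [(b, a) for a, b in reversed(pieces)]
    positions = {}  # genomic -> 1-based CDS coordinate
    k = 0
    for p, q in walk:
        step = 1 if q >= p else -1
        for off in range(abs(q - p) + 1):
            k += 1
            positions[p + step * off] = k
    covered = sorted(
        positions[g] for a, b in intervals for g in range(a, b + 1)
    )
    nt_lo, nt_hi = covered[0], covered[-1]
    if nt_hi - nt_lo + 1 != len(covered):
        raise ValueError("intervals do not form a contiguous CDS span")
    return (nt_lo - 1) // 3 + 1, nt_hi // 3


def classify_domain(
    intervals: list[tuple[int, int]], breakpoint: Breakpoint, strand: str
) -> str:
    """kept iff every interval lies wholly on the retained side.

    The 5' partner retains the transcription-upstream side of the
    breakpoint (breakpoint base included); the 3' partner retains the
    downstream side. Any overlap of the breakpoint or placement on the
    removed side means the domain is disrupted -> lost.
    """
    upstream_retained = breakpoint.role == "5p"
    keep_left = upstream_retained == (strand == "+")
    lo = min(a for a, _ in intervals)
    hi = max(b for _, b in intervals)
    if keep_left:
        return "kept" if hi <= breakpoint.position else "lost"
    return "kept" if lo >= breakpoint.position else "lost"


def go_rollup(classified: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Counts of kept/lost domains per GO label per fusion group.

    ``classified`` needs columns group, domain_id, status and the GO
    columns (go_bp, go_cc, go_mf); a domain contributes once per label;
    missing labels count under "unannotated".
    """
    rows = []
    for _, r in classified.iterrows():
        labels = set()
        for ont in ("go_bp", "go_cc", "go_mf"):
            v = r.get(ont)
            if pd.notna(v) and str(v):
                labels.add((ont, str(v)))
        if not labels:
            labels = {("none", "unannotated")}
        for ont, lab in labels:
            rows.append(
                {"group": r[group_col], "ontology": ont, "go_label": lab, "status": r["status"]}
            )
    if not rows:
        return pd.DataFrame(columns=["group", "ontology", "go_label", "kept", "lost"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["group", "ontology", "go_label", "status"])
        .size()
        .unstack("status", fill_value=0)
        .reset_index()
    )
    for col in ("kept", "lost"):
        if col not in out.columns:
            out[col] = 0
    return out[["group", "ontology", "go_label", "kept", "lost"]]


def _parse_bp(s: str) -> tuple[str, int, str]:
    chrom, pos, strand = str(s).rsplit(":", 2)
    return chrom, int(pos), strand


def analyze_catalog(
    records: pd.DataFrame,
    calls: pd.DataFrame,
    bundle: AnnotationBundle,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Domain impact for every surviving fusion.

    Uses the most frequent breakpoint pair per fusion across its
    supporting calls. Returns (per-domain classification table, GO
    rollup by fusion group).
    """
    sym2gid = bundle.symbol_to_gene_id()
    rows = []
    for _, rec in records.iterrows():
        sub = calls[(calls.gene5 == rec.gene5) & (calls.gene3 == rec.gene3)]
        if sub.empty:
            continue
        bp_pair = (
            sub.groupby(["left_breakpoint", "right_breakpoint"]).size().idxmax()
        )
        for gene_sym, role, bp_str in (
            (rec.gene5, "5p", bp_pair[0]),
            (rec.gene3, "3p", bp_pair[1]),
        ):
            gid = sym2gid.get(gene_sym)
            if gid is None:
                logger.warning("gene %s absent from annotation; skipped", gene_sym)
                continue
            chrom, pos, _ = _parse_bp(bp_str)
            strand = bundle.strand(gid)
            tx = representative_transcript(bundle, gid)
            bp = derive_breakpoint(gid, pos, role, tx, strand, chrom)
            doms = bundle.domains[bundle.domains.gene_id == gid]
            for _, d in doms.iterrows():
                ivals = map_domain_to_genome(int(d.aa_start), int(d.aa_end), tx, strand)
                status = classify_domain(ivals, bp, strand)
                rows.append(
                    {
                        "fusion_id": rec.fusion_id,
                        "group": rec.get("group", rec.fusion_id),
                        "gene": gene_sym,
                        "role": role,
                        "domain_id": d.domain_id,
                        "aa_start": int(d.aa_start),
                        "aa_end": int(d.aa_end),
                        "breakpoint": f"{bp.chrom}:{bp.position}",
                        "provenance": bp.provenance,
                        "status": status,
                        "go_bp": d.go_bp,
                        "go_cc": d.go_cc,
                        "go_mf": d.go_mf,
                    }
                )
    table = pd.DataFrame(rows)
    rollup = go_rollup(table) if len(table) else pd.DataFrame()
    return table, rollup


def write_bed(classified: pd.DataFrame, bundle: AnnotationBundle, path: str | Path) -> None:
    """Mapped domain intervals as BED (0-based half-open)."""
    sym2gid = bundle.symbol_to_gene_id()
    lines = []
    for _, r in classified.iterrows():
        gid = sym2gid[r.gene]
        tx = representative_transcript(bundle, gid)
        for a, b in map_domain_to_genome(r.aa_start, r.aa_end, tx, bundle.strand(gid)):
            lines.append(
                f"{bundle.chrom(gid)}\t{a - 1}\t{b}\t{r.gene}|{r.domain_id}|{r.status}"
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
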