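"""RBP motif scanning and GC/length-matched enrichment z-scores.

Sequence windows (default 200 nt) are taken on the exonic and intronic
side of each alternative splice site of an event, sense strand only
(RBP motifs act on pre-mRNA). Motifs are 6-mers (exact match) and
position frequency matrices (log-likelihood-ratio score against the
region's 0-order background at >= 80% of the maximum attainable score).
The observed per-motif frequency — the fraction of signal events with at
least one hit in a region class — is compared with its distribution over
100 control subsamples drawn from the non-significant event pool,
matched on the joint length x GC distribution of the signal set;
enrichment is called at z > 1.5.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import AnnotationBundle
from .splicing_events import SplicingEvent

logger = logging.getLogger(__name__)

__all__ = [
    "MotifDB",
    "EventRegion",
    "extract_event_regions",
    "scan_motifs",
    "match_controls",
    "enrichment_z",
    "run_enrichment",
]

BASES = "ACGT"


@dataclass
class MotifDB:
    """Per-RBP position frequency matrices and 6-mer sets."""

    pfms: dict = field(default_factory=dict)  # rbp -> list of 4 x L arrays (rows A,C,G,T)
    kmers: dict = field(default_factory=dict)  # rbp -> set of 6-mers

    def __post_init__(self) -> None:
        for rbp, mats in self.pfms.items():
            for m in mats:
                m = np.asarray(m, dtype=float)
                if m.shape[0] != 4 or not np.allclose(m.sum(axis=0), 1.0, atol=1e-6):
                    raise ValueError(f"PFM columns for {rbp} must sum to 1")
        for rbp, ks in self.kmers.items():
            for k in ks:
                if len(k) != 6 or set(k) - set(BASES):
                    raise ValueError(f"invalid 6-mer {k!r} for {rbp}")

    @property
    def rbps(self) -> list[str]:
        return sorted(set(self.pfms) | set(self.kmers))

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "motifs.pfm", "w") as fh:
            for rbp in sorted(self.pfms):
                for i, m in enumerate(self.pfms[rbp]):
                    fh.write(f">{rbp}_{i}\n")
                    for b, row in zip(BASES, np.asarray(m)):
                        fh.write(f"{b} [ " + " ".join(f"{v:.4f}" for v in row) + " ]\n")
        rows = [
            {"rbp": rbp, "kmer": k}
            for rbp in sorted(self.kmers)
            for k in sorted(self.kmers[rbp])
        ]
        pd.DataFrame(rows).to_csv(outdir / "kmers.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, indir: str | Path) -> "MotifDB":
        indir = Path(indir)
        pfms: dict[str, list] = {}
        name, rows = None, []
        for line in open(indir / "motifs.pfm"):
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    pfms.setdefault(name.rsplit("_", 1)[0], []).append(np.array(rows))
                name, rows = line[1:], []
            elif line:
                rows.append([float(x) for x in line.split("[")[1].rstrip(" ]").split()])
        if name is not None:
            pfms.setdefault(name.rsplit("_", 1)[0], []).append(np.array(rows))
        km = pd.read_csv(indir / "kmers.tsv", sep="\t")
        kmers: dict[str, set] = {}
        for rbp, k in zip(km.rbp, km.kmer):
            kmers.setdefault(str(rbp), set()).add(str(k))
        return cls(pfms=pfms, kmers=kmers)


@dataclass
class EventRegion:
    event_id: str
    region_class: str  # e.g. "site2_intronic"
    chrom: str
    start: int  # 1-based inclusive, genomic
    end: int
    strand: str
    sequence: str
    truncated: bool = False

    @property
    def gc(self) -> float:
        s = self.sequence
        return (s.count("G") + s.count("C")) / len(s) if s else 0.0


def extract_event_regions(
    events: list[SplicingEvent], bundle: AnnotationBundle, window: int = 200
) -> list[EventRegion]:
    """Windows on each side of every alternative splice site of each event.

    For every genomic splice-site coordinate of the event, one window
    upstream and one downstream (labelled by transcription direction:
    left/right swap on the minus strand). Sequences are sense-strand
    (reverse-complemented for minus-strand genes); windows overrunning a
    chromosome end are truncated and flagged.
    """
    out = []
    for ev in events:
        if ev.chrom not in bundle.sequences:
            raise ValueError(f"{ev.event_id}: chromosome {ev.chrom} missing from genome")
        chrom_len = len(bundle.sequences[ev.chrom])
        for i, pos in enumerate(ev.sites):
            for side in ("upstream", "downstream"):
                genomic_left = (side == "upstream") == (ev.strand == "+")
                if genomic_left:
                    start, end = pos - window, pos - 1
                else:
                    start, end = pos + 1, pos + window
                truncated = start < 1 or end > chrom_len
                start, end = max(1, start), min(chrom_len, end)
                if start > end:
                    continue
                seq = bundle.fetch(ev.chrom, start, end, ev.strand)
                out.append(
                    EventRegion(
                        event_id=ev.event_id,
                        region_class=f"site{i + 1}_{side}",
                        chrom=ev.chrom,
                        start=start,
                        end=end,
                        strand=ev.strand,
                        sequence=seq,
                        truncated=truncated,
                    )
                )
    return out


# ------------------------------------------------------------------- scanning


def _pfm_hits(seq: str, pfm: np.ndarray, score_fraction: float, pseudocount: float = 0.01) -> int:
    """Count positions where the log-likelihood-ratio score (PFM vs the
    region's 0-order base composition) reaches ``score_fraction`` of the
    maximum attainable score."""
    L = pfm.shape[1]
    n = len(seq)
    if n < L:
        return 0
    idx = np.array([BASES.find(c) for c in seq])
    bg = np.full(4, pseudocount)
    for b in range(4):
        bg[b] += (idx == b).sum()
    bg = bg / bg.sum()
    logodds = np.log2((pfm + pseudocount) / bg[:, None])
    maxscore = logodds.max(axis=0).sum()
    if maxscore <= 0:
        return 0
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    valid = (windows >= 0).all(axis=1)  # non-ACGT positions skipped
    scores = logodds[windows.clip(min=0), np.arange(L)].sum(axis=1)
    return int((valid & (scores >= score_fraction * maxscore)).sum())


def scan_motifs(
    regions: list[EventRegion],
    db: MotifDB,
    pfm_score_fraction: float = 0.8,
) -> pd.DataFrame:
    """Hit table: one row per region x motif with a positive hit count.

    6-mer hits are exact substring matches; PFM hits use the
    log-likelihood-ratio threshold. Sense strand only.
    """
    rows = []
    for reg in regions:
        seq = reg.sequence.upper()
        if set(seq) - set(BASES):
            logger.info("region %s/%s contains non-ACGT characters", reg.event_id, reg.region_class)
        for rbp in db.rbps:
            n = 0
            for k in db.kmers.get(rbp, ()):  # exact k-mer matches
                start = 0
                while True:
                    p = seq.find(k, start)
                    if p < 0:
                        break
                    n += 1
                    start = p + 1
            for pfm in db.pfms.get(rbp, ()):  # PFM matches
                n += _pfm_hits(seq, np.asarray(pfm, dtype=float), pfm_score_fraction)
            if n:
                rows.append(
                    {
                        "event_id": reg.event_id,
                        "region_class": reg.region_class,
                        "rbp": rbp,
                        "hits": n,
                    }
                )
    return pd.DataFrame(rows, columns=["event_id", "region_class", "rbp", "hits"])


# ------------------------------------------------------------------- controls


def _length_gc(regions: list[EventRegion]) -> pd.DataFrame:
    """Per event: total region length and mean GC."""
    df = pd.DataFrame(
        {
            "event_id": [r.event_id for r in regions],
            "length": [len(r.sequence) for r in regions],
            "gc": [r.gc for r in regions],
        }
    )
    return df.groupby("event_id").agg(length=("length", "sum"), gc=("gc", "mean"))


def match_controls(
    signal_events: list[str],
    pool_events: list[str],
    features: pd.DataFrame,
    n_samples: int = 100,
    n_bins: int = 4,
    seed: int = 0,
) -> list[list[str]]:
    """Draw ``n_samples`` control sets matching the signal's length x GC
    distribution by stratified sampling over quantile bins.

    ``features`` indexes events with columns length and gc. Sampling is
    without replacement within each subsample; an empty stratum falls
    back to the nearest populated bin with a warning.
    """
    signal_events = sorted(signal_events)
    pool_events = sorted(set(pool_events) - set(signal_events))
    if len(pool_events) < len(signal_events):
        raise ValueError("control pool smaller than the signal set")
    rng = np.random.default_rng(seed)
    sig = features.loc[signal_events]
    pool = features.loc[pool_events]

    def bin_edges(v):
        qs = np.quantile(sig[v], np.linspace(0, 1, n_bins + 1))
        qs[0], qs[-1] = -np.inf, np.inf
        return qs

    le, ge = bin_edges("length"), bin_edges("gc")
    sig_bin = list(
        zip(np.searchsorted(le, sig.length, side="left"), np.searchsorted(ge, sig.gc, side="left"))
    )
    pool_bin = pd.Series(
        list(
            zip(
                np.searchsorted(le, pool.length, side="left"),
                np.searchsorted(ge, pool.gc, side="left"),
            )
        ),
        index=pool.index,
    )
    need = pd.Series(sig_bin).value_counts().to_dict()
    by_bin = {b: list(idx) for b, idx in pool_bin.groupby(pool_bin).groups.items()}
    subsamples = []
    for _ in range(n_samples):
        chosen: list[str] = []
        taken: set[str] = set()
        for b, cnt in sorted(need.items()):
            cands = [e for e in by_bin.get(b, []) if e not in taken]
            if len(cands) < cnt:
                warnings.warn(f"stratum {b} underpopulated; nearest-bin fallback")
                extra = [e for e in pool.index if e not in taken and e not in cands]
                dist = [
                    abs(pool_bin[e][0] - b[0]) + abs(pool_bin[e][1] - b[1]) for e in extra
                ]
                extra = [e for _, e in sorted(zip(dist, extra))]
                cands = cands + extra[: cnt - len(cands)]
            pick = rng.choice(len(cands), size=cnt, replace=False)
            for i in pick:
                chosen.append(cands[i])
                taken.add(cands[i])
        subsamples.append(sorted(chosen))
    return subsamples


def _event_freq(hits: pd.DataFrame, events: list[str]) -> pd.DataFrame:
    """Fraction of events with >= 1 hit, per motif x region class."""
    events = set(events)
    sub = hits[hits.event_id.isin(events)]
    g = sub.groupby(["rbp", "region_class"]).event_id.nunique()
    return (g / max(len(events), 1)).rename("freq").reset_index()


def enrichment_z(
    hits: pd.DataFrame,
    signal_events: list[str],
    control_sets: list[list[str]],
    z_threshold: float = 1.5,
) -> pd.DataFrame:
    """z = (observed - control mean) / control SD per motif x region class.

    SD = 0 with observed equal to the constant gives z = 0; otherwise the
    z is flagged infinite with a warning.
    """
    obs = _event_freq(hits, signal_events).set_index(["rbp", "region_class"]).freq
    ctl = [
        _event_freq(hits, cs).set_index(["rbp", "region_class"]).freq for cs in control_sets
    ]
    keys = sorted(set(obs.index) | {k for c in ctl for k in c.index})
    rows = []
    for key in keys:
        o = float(obs.get(key, 0.0))
        cvals = np.array([float(c.get(key, 0.0)) for c in ctl])
        mu, sd = float(cvals.mean()), float(cvals.std(ddof=0))
        if sd == 0:
            if o == mu:
                z = 0.0
            else:
                z = np.inf if o > mu else -np.inf
                warnings.warn(f"zero control SD for {key} with observed != control")
        else:
            z = (o - mu) / sd
        rows.append(
            {
                "rbp": key[0],
                "region_class": key[1],
                "observed_freq": o,
                "control_mean": mu,
                "control_sd": sd,
                "z": z,
                "enriched": bool(z > z_threshold),
            }
        )
    return pd.DataFrame(rows)


def run_enrichment(
    events: list[SplicingEvent],
    significant_ids: list[str],
    bundle: AnnotationBundle,
    db: MotifDB,
    window: int = 200,
    n_samples: int = 100,
    seed: int = 0,
    z_threshold: float = 1.5,
) -> pd.DataFrame:
    """Full enrichment pass: regions, scan, matched controls, z-scores."""
    regions = extract_event_regions(events, bundle, window=window)
    hits = scan_motifs(regions, db)
    features = _length_gc(regions)
    sig = [e for e in significant_ids if e in features.index]
    pool = [e.event_id for e in events if e.event_id not in set(significant_ids) and e.event_id in features.index]
    controls = match_controls(sig, pool, features, n_samples=n_samples, seed=seed)
    return enrichment_z(hits, sig, controls, z_threshold=z_threshold)
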