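"""Fusion-call parsing and the evidence / artifact / recurrence / FAF cascade.

Fusion calls in STAR-Fusion-style TSV are filtered in four stages:

1. evidence: junction reads >= 1, spanning fragments >= 1, FFPM >= 0.1,
   large-anchor support ("YES_LDAS").
2. artifact block (order-invariant, call-level): pseudogene partners,
   paralogous pairs (>=70% identity list), immunoglobulin/hemoglobin
   pairs, and promiscuous genes (a gene fused to more than one distinct
   partner within one sample, its own reciprocal not counted).
3. recurrence block (fusion-level): normal-tissue panel, single-project
   fusions, fusions seen in fewer than ``min_patients`` patients.
   Fusions involving known leukemia genes bypass the normal-panel,
   single-project and promiscuity filters but never the patient-count rule.
4. fusion allele frequency (FAF): median FAF across supporting patients
   must exceed ``median_faf_min`` (strict), and the lower-FAF partner's
   median individual FAF must reach ``partner_median_min``.

FAF_i = F_i / (F_i + WT_i) per partner (F = junction reads, WT = wild-type
reads over the breakpoint); FAF is the mean of the two sides and is a
proxy for fusion clonality.

Survivors are classified (ALL > blood > solid > novel, unordered pair
match), grouped by the most recurrent partner gene ("<GENE>-r"), and the
groups are tested for pairwise mutual exclusivity with the probabilistic
co-occurrence model; groups exclusive with no other group collapse into
"Other".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cooccurrence_ppi import cooccur_test

logger = logging.getLogger(__name__)

__all__ = [
    "KnowledgeTables",
    "STAR_FUSION_V14",
    "parse_fusion_calls",
    "evidence_filter",
    "compute_faf",
    "artifact_filters",
    "recurrence_filters",
    "faf_threshold_filter",
    "classify_fusion",
    "group_by_partner",
    "exclusivity_grouping",
    "run_catalog",
    "CatalogResult",
]

# canonical column set used internally
CANONICAL_COLUMNS = [
    "sample_id",
    "cohort_id",
    "gene5",
    "gene3",
    "left_breakpoint",
    "right_breakpoint",
    "junction_reads",
    "spanning_frags",
    "ffpm",
    "large_anchor",
    "wt5_reads",
    "wt3_reads",
]

#: STAR-Fusion v1.4 dialect; wild-type read counts are caller extras and can
#: be given either as counts (wt5/wt3) or per-side allele-frequency columns
#: from which WT_i = F_i (1 - f_i) / f_i is inverted.
STAR_FUSION_V14 = {
    "fusion_name": "#FusionName",
    "junction_reads": "JunctionReadCount",
    "spanning_frags": "SpanningFragCount",
    "gene5": "LeftGene",
    "left_breakpoint": "LeftBreakpoint",
    "gene3": "RightGene",
    "right_breakpoint": "RightBreakpoint",
    "ffpm": "FFPM",
    "large_anchor": "LargeAnchorSupport",
    "sample_id": "sample_id",
    "cohort_id": "cohort_id",
    "wt5_reads": "wt5_reads",
    "wt3_reads": "wt3_reads",
    "faf_left": "faf_left",
    "faf_right": "faf_right",
}

ARTIFACT_FILTERS = ["pseudogene", "paralog", "immunoglobulin", "promiscuity"]
RECORD_FILTERS = ["normal_panel", "single_project", "min_patients", "faf_median", "faf_partner"]
ALL_FILTERS = ["evidence"] + ARTIFACT_FILTERS + RECORD_FILTERS


@dataclass
class KnowledgeTables:
    """Symbol-keyed knowledge used by the artifact/recurrence filters.

    All symbols are case-normalized to upper case; fusion pairs are
    unordered (frozenset) keys.
    """

    pseudogenes: set = field(default_factory=set)
    paralog_pairs: set = field(default_factory=set)  # of frozenset
    ig_hb_genes: set = field(default_factory=set)
    normal_panel_pairs: set = field(default_factory=set)  # of frozenset
    known_fusions: dict = field(default_factory=dict)  # frozenset -> class
    leukemia_genes: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.pseudogenes = {str(g).upper() for g in self.pseudogenes}
        self.ig_hb_genes = {str(g).upper() for g in self.ig_hb_genes}
        self.leukemia_genes = {str(g).upper() for g in self.leukemia_genes}
        self.paralog_pairs = {
            frozenset(str(g).upper() for g in p) for p in self.paralog_pairs
        }
        self.normal_panel_pairs = {
            frozenset(str(g).upper() for g in p) for p in self.normal_panel_pairs
        }
        self.known_fusions = {
            frozenset(str(g).upper() for g in p): c for p, c in self.known_fusions.items()
        }

    # ------------------------------------------------------------------ I/O

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"gene": sorted(self.pseudogenes)}).to_csv(
            outdir / "pseudogenes.tsv", sep="\t", index=False
        )
        pd.DataFrame({"gene": sorted(self.ig_hb_genes)}).to_csv(
            outdir / "ig_hb_genes.tsv", sep="\t", index=False
        )
        pd.DataFrame({"gene": sorted(self.leukemia_genes)}).to_csv(
            outdir / "leukemia_genes.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            sorted(sorted(p) for p in self.paralog_pairs), columns=["gene_a", "gene_b"]
        ).to_csv(outdir / "paralogs.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(sorted(p) for p in self.normal_panel_pairs), columns=["gene_a", "gene_b"]
        ).to_csv(outdir / "normal_panel.tsv", sep="\t", index=False)
        kf = pd.DataFrame(
            sorted([*sorted(p), c] for p, c in self.known_fusions.items()),
            columns=["gene_a", "gene_b", "class"],
        )
        kf.to_csv(outdir / "known_fusions.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, indir: str | Path) -> "KnowledgeTables":
        indir = Path(indir)

        def genes(name):
            df = pd.read_csv(indir / name, sep="\t")
            return set(df["gene"].astype(str))

        def pairs(name):
            df = pd.read_csv(indir / name, sep="\t")
            return {frozenset((a, b)) for a, b in zip(df.gene_a, df.gene_b)}

        kf = pd.read_csv(indir / "known_fusions.tsv", sep="\t")
        known = {
            frozenset((a, b)): c for a, b, c in zip(kf.gene_a, kf.gene_b, kf["class"])
        }
        return cls(
            pseudogenes=genes("pseudogenes.tsv"),
            paralog_pairs=pairs("paralogs.tsv"),
            ig_hb_genes=genes("ig_hb_genes.tsv"),
            normal_panel_pairs=pairs("normal_panel.tsv"),
            known_fusions=known,
            leukemia_genes=genes("leukemia_genes.tsv"),
        )


# ---------------------------------------------------------------------- parse


def parse_fusion_calls(path: str | Path, dialect: dict | None = None) -> pd.DataFrame:
    """Parse a fusion-caller TSV into the canonical call table.

    The dialect maps canonical field names to the file's column names
    (default STAR-Fusion v1.4). Wild-type support must come either from
    wild-type read-count columns or per-side allele-frequency columns.
    Reciprocal calls (B::A vs A::B) are kept distinct.
    """
    dialect = dict(STAR_FUSION_V14 if dialect is None else dialect)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    mandatory = [
        "junction_reads",
        "spanning_frags",
        "gene5",
        "gene3",
        "left_breakpoint",
        "right_breakpoint",
        "ffpm",
        "large_anchor",
        "sample_id",
    ]
    missing = [dialect[k] for k in mandatory if dialect[k] not in raw.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")

    has_wt = dialect.get("wt5_reads") in raw.columns and dialect.get("wt3_reads") in raw.columns
    has_faf = dialect.get("faf_left") in raw.columns and dialect.get("faf_right") in raw.columns
    if not has_wt and not has_faf:
        raise ValueError(
            "dialect must provide wild-type read counts (wt5_reads/wt3_reads) "
            "or per-side allele-frequency columns (faf_left/faf_right)"
        )

    def numeric(col, kind=float):
        vals = []
        for i, v in enumerate(raw[dialect[col]]):
            try:
                vals.append(kind(v))
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric value {v!r} for column {dialect[col]} at line {i + 2}"
                ) from None
        return np.asarray(vals)

    out = pd.DataFrame(
        {
            "sample_id": raw[dialect["sample_id"]].astype(str),
            "cohort_id": (
                raw[dialect["cohort_id"]].astype(str)
                if dialect.get("cohort_id") in raw.columns
                else "NA"
            ),
            "gene5": raw[dialect["gene5"]].astype(str).str.split("^").str[0],
            "gene3": raw[dialect["gene3"]].astype(str).str.split("^").str[0],
            "left_breakpoint": raw[dialect["left_breakpoint"]].astype(str),
            "right_breakpoint": raw[dialect["right_breakpoint"]].astype(str),
            "junction_reads": numeric("junction_reads", int),
            "spanning_frags": numeric("spanning_frags", int),
            "ffpm": numeric("ffpm"),
            "large_anchor": raw[dialect["large_anchor"]].astype(str) == "YES_LDAS",
        }
    )
    if (out.gene5 == out.gene3).any():
        bad = out.index[out.gene5 == out.gene3][0]
        raise ValueError(f"self-fusion at line {bad + 2}: {out.gene5[bad]}")
    if has_wt:
        out["wt5_reads"] = numeric("wt5_reads", int)
        out["wt3_reads"] = numeric("wt3_reads", int)
    else:
        f5, f3 = numeric("faf_left"), numeric("faf_right")
        for name, f in (("faf_left", f5), ("faf_right", f3)):
            if ((f < 0) | (f > 1)).any():
                raise ValueError(f"{name} outside [0,1]")
        j = out.junction_reads.to_numpy().astype(float)
        if ((f5 == 0) & (j > 0)).any() or ((f3 == 0) & (j > 0)).any():
            raise ValueError("allele frequency 0 with non-zero junction reads")
        with np.errstate(divide="ignore", invalid="ignore"):
            out["wt5_reads"] = np.where(f5 > 0, np.round(j * (1 - f5) / np.where(f5 > 0, f5, 1)), 0).astype(int)
            out["wt3_reads"] = np.where(f3 > 0, np.round(j * (1 - f3) / np.where(f3 > 0, f3, 1)), 0).astype(int)
    if (out[["junction_reads", "spanning_frags", "wt5_reads", "wt3_reads"]] < 0).any().any():
        raise ValueError("negative read counts")
    return out[CANONICAL_COLUMNS]


# -------------------------------------------------------------------- filters


def evidence_filter(calls: pd.DataFrame) -> pd.DataFrame:
    """Pass/fail per call with the first failing criterion as reason."""
    ok_j = calls.junction_reads >= 1
    ok_s = calls.spanning_frags >= 1
    ok_f = calls.ffpm >= 0.1
    ok_a = calls.large_anchor.astype(bool)
    reason = np.select(
        [~ok_j, ~ok_s, ~ok_f, ~ok_a],
        ["junction_reads", "spanning_frags", "ffpm", "large_anchor"],
        default="",
    )
    return pd.DataFrame({"pass": ok_j & ok_s & ok_f & ok_a, "reason": reason}, index=calls.index)


def compute_faf(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-call FAF_L, FAF_R and their mean; FAF_i = 0 when F_i + WT_i = 0."""
    for c in ("junction_reads", "wt5_reads", "wt3_reads"):
        if (calls[c] < 0).any():
            raise ValueError(f"negative counts in column {c}")
    f = calls.junction_reads.to_numpy(dtype=float)
    wt5 = calls.wt5_reads.to_numpy(dtype=float)
    wt3 = calls.wt3_reads.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        faf_l = np.where(f + wt5 > 0, f / (f + wt5), 0.0)
        faf_r = np.where(f + wt3 > 0, f / (f + wt3), 0.0)
    out = calls.copy()
    out["faf_l"] = faf_l
    out["faf_r"] = faf_r
    out["faf"] = (faf_l + faf_r) / 2.0
    return out


def _pair(a: str, b: str) -> frozenset:
    return frozenset((str(a).upper(), str(b).upper()))


def artifact_filters(calls: pd.DataFrame, knowledge: KnowledgeTables) -> pd.DataFrame:
    """Call-level artifact filters, each evaluated independently.

    Returns a DataFrame of boolean *fail* flags (one column per filter).
    Promiscuity: a gene partnered with more than one distinct other gene
    within the same sample fails all its calls in that sample; the exact
    reciprocal pair does not count as a second partner, and calls
    involving known leukemia genes are exempt (rescue).
    """
    g5u = calls.gene5.str.upper()
    g3u = calls.gene3.str.upper()
    fail = pd.DataFrame(index=calls.index)
    fail["pseudogene"] = g5u.isin(knowledge.pseudogenes) | g3u.isin(knowledge.pseudogenes)
    pairs = [_pair(a, b) for a, b in zip(calls.gene5, calls.gene3)]
    fail["paralog"] = [p in knowledge.paralog_pairs for p in pairs]
    fail["immunoglobulin"] = g5u.isin(knowledge.ig_hb_genes) & g3u.isin(knowledge.ig_hb_genes)

    promiscuous = np.zeros(len(calls), dtype=bool)
    for _, idx in calls.groupby("sample_id", sort=False).groups.items():
        sub = calls.loc[idx]
        partners: dict[str, set] = {}
        for a, b in zip(sub.gene5.str.upper(), sub.gene3.str.upper()):
            partners.setdefault(a, set()).add(b)
            partners.setdefault(b, set()).add(a)
        bad_genes = {g for g, ps in partners.items() if len(ps) > 1}
        if bad_genes:
            mask = (
                sub.gene5.str.upper().isin(bad_genes) | sub.gene3.str.upper().isin(bad_genes)
            ) & ~(
                sub.gene5.str.upper().isin(knowledge.leukemia_genes)
                | sub.gene3.str.upper().isin(knowledge.leukemia_genes)
            )
            promiscuous[calls.index.get_indexer(sub.index[mask])] = True
    fail["promiscuity"] = promiscuous
    return fail


def aggregate_records(calls: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-sample calls into per-fusion records (ordered pairs)."""
    if "faf" not in calls.columns:
        calls = compute_faf(calls)
    rows = []
    for (g5, g3), sub in calls.groupby(["gene5", "gene3"], sort=True):
        rows.append(
            {
                "fusion_id": f"{g5}::{g3}",
                "gene5": g5,
                "gene3": g3,
                "n_patients": sub.sample_id.nunique(),
                "n_cohorts": sub.cohort_id.nunique(),
                "median_faf": float(sub.faf.median()),
                "median_faf_l": float(sub.faf_l.median()),
                "median_faf_r": float(sub.faf_r.median()),
                "samples": ",".join(sorted(sub.sample_id.unique())),
            }
        )
    cols = [
        "fusion_id", "gene5", "gene3", "n_patients", "n_cohorts",
        "median_faf", "median_faf_l", "median_faf_r", "samples",
    ]
    return pd.DataFrame(rows, columns=cols)


def recurrence_filters(
    records: pd.DataFrame, knowledge: KnowledgeTables, min_patients: int = 5
) -> pd.DataFrame:
    """Normal-panel / single-project / patient-count filters (fail flags).

    Known-leukemia-gene fusions bypass the normal-panel and single-project
    filters; the >= min_patients rule applies to every fusion.
    """
    if min_patients < 1:
        raise ValueError("min_patients must be >= 1")
    rescued = records.gene5.str.upper().isin(knowledge.leukemia_genes) | records.gene3.str.upper().isin(
        knowledge.leukemia_genes
    )
    pairs = [_pair(a, b) for a, b in zip(records.gene5, records.gene3)]
    fail = pd.DataFrame(index=records.index)
    fail["normal_panel"] = np.asarray([p in knowledge.normal_panel_pairs for p in pairs]) & ~rescued
    fail["single_project"] = (records.n_cohorts < 2).to_numpy() & ~rescued.to_numpy()
    fail["min_patients"] = (records.n_patients < min_patients).to_numpy()
    return fail


def faf_threshold_filter(
    records: pd.DataFrame,
    median_faf_min: float = 0.1,
    partner_median_min: float = 0.01,
) -> pd.DataFrame:
    """FAF thresholds (fail flags): median FAF strictly above
    ``median_faf_min`` and the lower partner median at least
    ``partner_median_min``."""
    fail = pd.DataFrame(index=records.index)
    fail["faf_median"] = ~(records.median_faf > median_faf_min)
    lower = np.minimum(records.median_faf_l, records.median_faf_r)
    fail["faf_partner"] = ~(lower >= partner_median_min)
    return fail


def classify_fusion(gene5: str, gene3: str, knowledge: KnowledgeTables) -> str:
    """Class of a fusion pair: ALL > blood > solid > novel, unordered match."""
    cls = knowledge.known_fusions.get(_pair(gene5, gene3))
    return cls if cls in {"ALL", "blood", "solid"} else "novel"


def group_by_partner(records: pd.DataFrame) -> pd.Series:
    """Group label per fusion: the member gene supported by more patients
    across all retained fusions, labeled "<GENE>-r"; ties lexicographic."""
    counts: dict[str, int] = {}
    for _, r in records.iterrows():
        for g in (r.gene5, r.gene3):
            counts[g] = counts.get(g, 0) + int(r.n_patients)
    labels = []
    for _, r in records.iterrows():
        a, b = r.gene5, r.gene3
        if counts[a] > counts[b]:
            top = a
        elif counts[b] > counts[a]:
            top = b
        else:
            top = min(a, b)
        labels.append(f"{top}-r")
    return pd.Series(labels, index=records.index, name="group")


def exclusivity_grouping(presence: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Relabel groups with no mutually exclusive partner as "Other".

    ``presence`` is a groups x samples binary matrix. For each pair of
    groups the probabilistic co-occurrence test is applied; a group is
    retained when P(observed or fewer co-occurrences) < alpha against at
    least one other group.
    """
    groups = list(presence.index)
    labels = pd.Series(groups, index=groups, name="exclusivity_label")
    n = presence.shape[1]
    for g in groups:
        row = presence.loc[g].to_numpy().astype(int)
        if row.sum() <= 1:
            warnings.warn(f"fusion group {g} present in <=1 sample; relabeled Other")
            labels[g] = "Other"
            continue
        exclusive = False
        for h in groups:
            if h == g:
                continue
            other = presence.loc[h].to_numpy().astype(int)
            if other.sum() == 0:
                continue
            res = cooccur_test(row, other)
            if res.p_lt < alpha:
                exclusive = True
                break
        if not exclusive:
            labels[g] = "Other"
    return labels


# ----------------------------------------------------------------- orchestrate


@dataclass
class CatalogResult:
    records: pd.DataFrame  # surviving fusions with class/group/medians
    trail: pd.DataFrame  # per-call filter trail
    surviving_calls: pd.DataFrame
    presence: pd.DataFrame  # group x sample binary matrix
    exclusivity_labels: pd.Series

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(outdir / "fusion_catalog.tsv", sep="\t", index=False)
        self.trail.to_csv(outdir / "fusion_filter_trail.tsv", sep="\t", index=False)
        self.presence.to_csv(outdir / "fusion_presence_matrix.tsv", sep="\t")


def run_catalog(
    calls: pd.DataFrame,
    knowledge: KnowledgeTables,
    min_patients: int = 5,
    median_faf_min: float = 0.1,
    partner_median_min: float = 0.01,
    exclusivity_alpha: float = 0.05,
    all_samples: list[str] | None = None,
) -> CatalogResult:
    """Run the full cascade and return survivors plus a per-call trail."""
    calls = compute_faf(calls.reset_index(drop=True))
    trail = pd.DataFrame(
        {
            "sample_id": calls.sample_id,
            "fusion_id": calls.gene5 + "::" + calls.gene3,
        }
    )
    ev = evidence_filter(calls)
    trail["evidence"] = np.where(ev["pass"], "pass", "fail:" + ev.reason)
    alive = ev["pass"].to_numpy()

    art = artifact_filters(calls.loc[alive], knowledge)
    for f in ARTIFACT_FILTERS:
        col = np.full(len(calls), "skipped", dtype=object)
        col[np.flatnonzero(alive)] = np.where(art[f], "fail", "pass")
        trail[f] = col
    alive_idx = np.flatnonzero(alive)[~art.to_numpy().any(axis=1)]
    alive = np.zeros(len(calls), dtype=bool)
    alive[alive_idx] = True

    records = aggregate_records(calls.loc[alive])
    rec_fail = recurrence_filters(records, knowledge, min_patients)
    faf_fail = faf_threshold_filter(records, median_faf_min, partner_median_min)
    rec_fail = pd.concat([rec_fail, faf_fail], axis=1)
    fusion_status = {
        r.fusion_id: {f: ("fail" if rec_fail.loc[i, f] else "pass") for f in RECORD_FILTERS}
        for i, r in records.iterrows()
    }
    for f in RECORD_FILTERS:
        col = np.full(len(calls), "skipped", dtype=object)
        for i in np.flatnonzero(alive):
            fid = f"{calls.gene5[i]}::{calls.gene3[i]}"
            col[i] = fusion_status[fid][f]
        trail[f] = col

    # first failing filter in cascade order
    removed_by = np.full(len(calls), "", dtype=object)
    order = ["evidence"] + ARTIFACT_FILTERS + RECORD_FILTERS
    for i in range(len(calls)):
        for f in order:
            v = trail.loc[i, f]
            if isinstance(v, str) and v.startswith("fail"):
                removed_by[i] = f
                break
    trail["removed_by"] = removed_by

    keep_records = records.loc[~rec_fail.any(axis=1)].reset_index(drop=True)
    surviving_ids = set(keep_records.fusion_id)
    surv = calls.loc[alive]
    surv = surv[(surv.gene5 + "::" + surv.gene3).isin(surviving_ids)].reset_index(drop=True)

    keep_records["class"] = [
        classify_fusion(a, b, knowledge) for a, b in zip(keep_records.gene5, keep_records.gene3)
    ]
    keep_records["group"] = group_by_partner(keep_records)

    samples = sorted(all_samples) if all_samples is not None else sorted(calls.sample_id.unique())
    groups = sorted(keep_records.group.unique())
    presence = pd.DataFrame(0, index=groups, columns=samples, dtype=int)
    fid_group = dict(zip(keep_records.fusion_id, keep_records.group))
    for _, c in surv.iterrows():
        presence.loc[fid_group[f"{c.gene5}::{c.gene3}"], c.sample_id] = 1

    if len(groups) >= 2:
        labels = exclusivity_grouping(presence, exclusivity_alpha)
    else:
        labels = pd.Series(groups, index=groups, name="exclusivity_label")
    keep_records["exclusivity_label"] = keep_records.group.map(labels)

    return CatalogResult(
        records=keep_records,
        trail=trail,
        surviving_calls=surv,
        presence=presence,
        exclusivity_labels=labels,
    )
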