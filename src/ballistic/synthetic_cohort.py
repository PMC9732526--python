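"""Synthetic multi-cohort B-ALL-like datasets with a machine-readable truth ledger.

One call to :func:`generate_cohort` produces a self-consistent bundle:
annotation (GTF-able gene models with CDS and protein domains on a
synthetic genome), STAR-Fusion-style fusion calls (true fusion groups
with reciprocal pairs plus planted artifact calls of eight classes),
a transcript TPM matrix (negative-binomial gene expression with cohort
batch offsets, sex/tissue effects, planted differential expression and a
planted prognostic program), two-isoform splicing events with planted
dPSI between latent risk strata, survival outcomes whose hazard is
log-linear in the planted prognostic expression, an RBP motif database
with one 6-mer planted into the donor-intron flank of selected events, a
STRING-style PPI table with a hub RBP wired to the signature, and the
knowledge tables the fusion cascade consumes.

The TruthLedger records every planted signal so each downstream stage
has an exact oracle. Identical spec + seed reproduces the bundle
byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import AnnotationBundle, Transcript
from .fusion_catalog import KnowledgeTables
from .motif_enrichment import MotifDB
from .splicing_events import se_event_id

__all__ = ["CohortSpec", "TruthLedger", "CohortBundle", "generate_cohort", "sample_qc"]

# ----------------------------------------------------------------- spec

#: canonical fusion groups: hub gene, (main partner, secondary partner),
#: class of each pair in the knowledge catalog, and whether the main pair
#: co-occurs with its reciprocal in part of the patients
FUSION_GROUPS = {
    "KMT2A-r": {
        "hub": "KMT2A",
        "partners": ("AFF1", "MLLT3"),
        "classes": ("ALL", "ALL"),
        "reciprocal": True,
    },
    "ETV6-r": {
        "hub": "ETV6",
        "partners": ("RUNX1", "ABL2"),
        "classes": ("ALL", "blood"),
        "reciprocal": True,
    },
    "TCF3-r": {
        "hub": "TCF3",
        "partners": ("PBX1", "ZNF384"),
        "classes": ("ALL", "blood"),
        "reciprocal": False,
    },
    "PAX5-r": {
        "hub": "PAX5",
        "partners": ("JAK2", "NOL4L"),
        "classes": ("ALL", "novel"),
        "reciprocal": False,
    },
    "BCR-r": {
        "hub": "BCR",
        "partners": ("ABL1", "FGFR1"),
        "classes": ("ALL", "solid"),
        "reciprocal": False,
    },
}

ARTIFACT_CLASSES = (
    "pseudogene",
    "paralog",
    "immunoglobulin",
    "promiscuous",
    "normal_panel",
    "single_project",
    "low_faf",
    "low_recurrence",
)

_PSEUDO_PAIRS = [("RPL21P1", "ACIN1"), ("GAPDHP1", "SMARCA4"), ("FTH1P3", "NCOA2"), ("HMGB1P1", "ARID1B")]
_PARALOG_PAIRS = [("HSPA1A", "HSPA1B"), ("DDX3X", "DDX3Y"), ("UBA52", "RPS27A")]
_IG_PAIRS = [("IGHM", "IGHG1"), ("IGKC", "IGLC2"), ("HBB", "HBD")]
_PROM_HUB = "FLNA"
_PROM_PARTNERS = ["PRMA", "PRMB", "PRMC", "PRMD"]
_NORMAL_PAIRS = [("CTBS", "GNG5"), ("TFG", "ADGRG7"), ("CHFR", "GOLGA3")]
_SINGLE_PROJECT_PAIRS = [("SPR1A", "SPR1B"), ("SPR2A", "SPR2B")]
_LOW_FAF_PAIRS = [("LFA1", "LFB1"), ("LFA2", "LFB2")]
_LOW_REC_PAIRS = [(f"LRA{i}", f"LRB{i}") for i in range(1, 6)]

#: probability a patient of each group falls in the latent high-risk stratum
RISK_BY_GROUP = {"KMT2A-r": 0.85, "ETV6-r": 0.15, "TCF3-r": 0.5, "PAX5-r": 0.5, "BCR-r": 0.5, None: 0.45}


def _default_freqs() -> dict:
    return {"KMT2A-r": 0.20, "ETV6-r": 0.16, "TCF3-r": 0.08, "PAX5-r": 0.06, "BCR-r": 0.05}


def _default_artifact_rates() -> dict:
    return {
        "pseudogene": 0.30,
        "paralog": 0.20,
        "immunoglobulin": 0.20,
        "promiscuous": 0.15,
        "normal_panel": 0.20,
        "single_project": 0.10,
        "low_faf": 0.10,
        "low_recurrence": 0.05,
    }


@dataclass
class CohortSpec:
    """Study conditions for one synthetic multi-cohort dataset."""

    n_cohorts: int = 5
    patients_per_cohort: int = 60
    fusion_group_freqs: dict = field(default_factory=_default_freqs)
    artifact_rates: dict = field(default_factory=_default_artifact_rates)
    n_genes: int = 600
    n_prognostic_genes: int = 40
    prognostic_log_hazard: float = 4.0  # per SD of the planted-gene score
    de_log_fc: float = 1.5  # planted log2 fold-change
    n_events: int = 200
    planted_event_fraction: float = 0.30
    motif_planting_fraction: float = 0.60
    delta_psi_planted: float = 0.30
    planted_motif: str = "TGCATG"
    censoring_rate: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cohorts", "patients_per_cohort", "n_genes", "n_prognostic_genes", "n_events"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.delta_psi_planted < 1:
            raise ValueError("delta_psi_planted must lie in (0, 1)")
        if not 0 <= self.censoring_rate <= 1:
            raise ValueError("censoring_rate must lie in [0, 1]")
        for g, p in self.fusion_group_freqs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"fusion_group_freqs[{g}] outside [0, 1]")
            if g not in FUSION_GROUPS:
                raise ValueError(f"unknown fusion group {g}")
        if sum(self.fusion_group_freqs.values()) > 1 + 1e-9:
            raise ValueError("fusion_group_freqs must sum to <= 1")
        for c, r in self.artifact_rates.items():
            if c not in ARTIFACT_CLASSES:
                raise ValueError(f"unknown artifact class {c}")
            if r < 0:
                raise ValueError(f"artifact_rates[{c}] must be >= 0")
        n_special = self.n_prognostic_genes + 60 + self.n_events
        if n_special > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for n_prognostic_genes="
                f"{self.n_prognostic_genes} + 60 contrast-DE genes + n_events={self.n_events}"
            )
        if set(self.planted_motif) - set("ACGT") or len(self.planted_motif) != 6:
            raise ValueError("planted_motif must be a 6-mer over ACGT")


# --------------------------------------------------------------- truth ledger


@dataclass
class TruthLedger:
    """Record of every planted signal; the oracle for all tests."""

    true_fusions_by_sample: dict = field(default_factory=dict)  # sample -> [fusion_id]
    artifact_calls_by_class: dict = field(default_factory=dict)  # class -> [[sample, fusion_id]]
    fusion_group_by_sample: dict = field(default_factory=dict)  # sample -> group | None
    prognostic_gene_ids: list = field(default_factory=list)
    de_gene_ids: dict = field(default_factory=dict)  # contrast -> {"up": [...], "down": [...]}
    event_ids_planted_dpsi: list = field(default_factory=list)
    motif_bearing_event_ids: list = field(default_factory=list)
    risk_labels: dict = field(default_factory=dict)  # sample -> "high" | "low"
    survival_params: dict = field(default_factory=dict)  # sample -> {hazard, time, event}
    planted_motif: str = ""
    planted_rbp: str = ""
    hub_gene: str = ""

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLedger":
        with open(path) as fh:
            return cls(**json.load(fh))


# -------------------------------------------------------------------- bundle


@dataclass
class CohortBundle:
    spec: CohortSpec
    annotation: AnnotationBundle
    fusion_calls: pd.DataFrame  # canonical columns (fusion_catalog dialect)
    tpm: pd.DataFrame  # transcripts x samples
    clinical: pd.DataFrame  # indexed by sample_id
    read_stats: pd.DataFrame
    knowledge: KnowledgeTables
    gene_sets: dict  # set name -> list of gene ids
    motif_db: MotifDB
    ppi: pd.DataFrame
    ledger: TruthLedger

    def write(self, outdir: str | Path) -> None:
        """Write every artefact in its standard on-disk format."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.annotation.write_gtf(out / "annotation.gtf")
        self.annotation.write_fasta(out / "genome.fa")
        self.annotation.write_domains(out / "domains.tsv")
        star = pd.DataFrame(
            {
                "#FusionName": self.fusion_calls.gene5 + "--" + self.fusion_calls.gene3,
                "JunctionReadCount": self.fusion_calls.junction_reads,
                "SpanningFragCount": self.fusion_calls.spanning_frags,
                "LeftGene": self.fusion_calls.gene5,
                "LeftBreakpoint": self.fusion_calls.left_breakpoint,
                "RightGene": self.fusion_calls.gene3,
                "RightBreakpoint": self.fusion_calls.right_breakpoint,
                "FFPM": self.fusion_calls.ffpm,
                "LargeAnchorSupport": np.where(self.fusion_calls.large_anchor, "YES_LDAS", "NO_LDAS"),
                "sample_id": self.fusion_calls.sample_id,
                "cohort_id": self.fusion_calls.cohort_id,
                "wt5_reads": self.fusion_calls.wt5_reads,
                "wt3_reads": self.fusion_calls.wt3_reads,
            }
        )
        star.to_csv(out / "fusion_calls.tsv", sep="\t", index=False, float_format="%.6g")
        self.tpm.to_csv(out / "transcript_tpm.tsv", sep="\t", float_format="%.6g")
        self.clinical.to_csv(out / "clinical.tsv", sep="\t")
        self.read_stats.to_csv(out / "read_stats.tsv", sep="\t", index=False)
        self.knowledge.write(out / "knowledge")
        with open(out / "gene_sets.gmt", "w") as fh:
            for name in sorted(self.gene_sets):
                fh.write("\t".join([name, "synthetic"] + sorted(self.gene_sets[name])) + "\n")
        self.motif_db.write(out / "motifs")
        self.ppi.to_csv(out / "ppi_edges.tsv", sep="\t", index=False)
        self.ledger.to_json(out / "truth_ledger.json")


# ------------------------------------------------------------------ QC


def sample_qc(read_stats: pd.DataFrame) -> tuple[list, pd.DataFrame]:
    """Retain samples with mapped fraction >= 0.25 and >= 5M mapped reads.

    Boundaries are inclusive ("at least"). Returns the retained sample
    ids and an exclusion log naming the failed criterion per sample.
    """
    for col in ("sample_id", "mapped_fraction", "mapped_reads"):
        if col not in read_stats.columns:
            raise ValueError(f"read_stats missing column {col}")
    if read_stats.sample_id.isna().any() or read_stats[["mapped_fraction", "mapped_reads"]].isna().any().any():
        bad = read_stats.loc[read_stats.isna().any(axis=1), "sample_id"].tolist()
        raise ValueError(f"missing QC stats for sample(s): {bad}")
    ok_frac = read_stats.mapped_fraction >= 0.25
    ok_reads = read_stats.mapped_reads >= 5_000_000
    reason = np.select(
        [~ok_frac & ~ok_reads, ~ok_frac, ~ok_reads],
        ["mapped_fraction,mapped_reads", "mapped_fraction", "mapped_reads"],
        default="",
    )
    log = pd.DataFrame(
        {"sample_id": read_stats.sample_id, "retained": ok_frac & ok_reads, "reason": reason}
    )
    return log.loc[log.retained, "sample_id"].tolist(), log


# ----------------------------------------------------------------- generation


def _make_gene(
    rng, gene_id, symbol, chrom, cursor, strand, n_exons, two_isoform, category
):
    """One gene model starting at ``cursor``; returns (gene row, transcripts, next cursor)."""
    exon_lens = rng.integers(90, 220, size=n_exons)
    intron_lens = rng.integers(500, 900, size=n_exons - 1)
    exons = []
    pos = cursor
    for i in range(n_exons):
        exons.append((pos, pos + int(exon_lens[i]) - 1))
        pos = exons[-1][1] + 1 + (int(intron_lens[i]) if i < n_exons - 1 else 0)
    start, end = exons[0][0], exons[-1][1]

    def cds_span(exs):
        # exonic positions from offset 10 (genomic-left), trimmed to 3k length
        total = sum(b - a + 1 for a, b in exs)
        usable = total - 20
        k = (usable // 3) * 3
        # walk to genomic coordinates of exonic offsets 10 and 10+k-1
        flat_needed = [10, 10 + k - 1]
        coords = []
        seen = 0
        for a, b in exs:
            ln = b - a + 1
            for target in flat_needed:
                if seen <= target < seen + ln:
                    coords.append(a + (target - seen))
            seen += ln
        return coords[0], coords[1]

    transcripts = []
    t_main = Transcript(f"{gene_id}.t1", gene_id, exons)
    t_main.cds_start, t_main.cds_end = cds_span(exons)
    transcripts.append(t_main)
    cassette = None
    if two_isoform:
        ci = n_exons // 2
        cassette = exons[ci]
        skip = [e for k, e in enumerate(exons) if k != ci]
        t_alt = Transcript(f"{gene_id}.t2", gene_id, skip)
        t_alt.cds_start, t_alt.cds_end = cds_span(skip)
        transcripts.append(t_alt)
    row = {
        "symbol": symbol,
        "chrom": chrom,
        "strand": strand,
        "biotype": "protein_coding",
        "start": start,
        "end": end,
        "category": category,
    }
    return row, transcripts, cassette, end + 300


def _faf_counts(rng, mean_faf_a, mean_faf_b):
    """Junction/spanning/wt read counts realizing per-side FAF targets."""
    junction = int(5 + rng.poisson(10))
    spanning = int(2 + rng.poisson(6))
    f5 = float(np.clip(rng.beta(mean_faf_a, mean_faf_b), 0.005, 0.95))
    f3 = float(np.clip(rng.beta(mean_faf_a, mean_faf_b), 0.005, 0.95))
    wt5 = int(round(junction * (1 - f5) / f5))
    wt3 = int(round(junction * (1 - f3) / f3))
    ffpm = float(np.round(rng.uniform(0.15, 3.0), 3))
    return junction, spanning, wt5, wt3, ffpm


def generate_cohort(spec: CohortSpec) -> CohortBundle:
    """Generate the full bundle; deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    # ---------------- gene plan
    n_prog = spec.n_prognostic_genes
    prog_symbols = ["SRRM1", "RRP8", "RRP15", "UTP20", "BOP1", "DHX37"]
    plan = []  # (gene_id, symbol, category, two_isoform)
    for i in range(spec.n_genes):
        gid = f"G{i + 1:04d}"
        if i < n_prog:
            sym = prog_symbols[i] if i < len(prog_symbols) else f"PRG{i + 1:03d}"
            cat = "prognostic"
        elif i < n_prog + 30:
            sym, cat = f"DEU{i - n_prog + 1:03d}", "de_up"
        elif i < n_prog + 60:
            sym, cat = f"DED{i - n_prog - 30 + 1:03d}", "de_down"
        elif i < n_prog + 60 + spec.n_events:
            sym, cat = f"EVG{i - n_prog - 60 + 1:03d}", "event"
        else:
            sym, cat = f"BGD{i + 1:04d}", "background"
        plan.append((gid, sym, cat, cat == "event"))
    fusion_symbols = []
    for g in FUSION_GROUPS.values():
        fusion_symbols.append(g["hub"])
        fusion_symbols.extend(g["partners"])
    artifact_symbols = sorted(
        {s for p in _PSEUDO_PAIRS + _PARALOG_PAIRS + _IG_PAIRS + _NORMAL_PAIRS
         + _SINGLE_PROJECT_PAIRS + _LOW_FAF_PAIRS + _LOW_REC_PAIRS for s in p}
        | {_PROM_HUB, *_PROM_PARTNERS}
    )
    for j, sym in enumerate(fusion_symbols):
        plan.append((f"F{j + 1:03d}", sym, "fusion", False))
    for j, sym in enumerate(artifact_symbols):
        plan.append((f"A{j + 1:03d}", sym, "artifact", False))

    # ---------------- annotation
    chrom_cap = 1_000_000
    gene_rows, transcripts, cassettes = {}, {}, {}
    chrom_i, cursor = 1, 1_000
    chrom_lens: dict[str, int] = {}
    for gid, sym, cat, two in plan:
        n_exons = int(rng.integers(4, 7)) if (two or cat == "fusion") else int(rng.integers(3, 6))
        strand = "+" if rng.random() < 0.5 else "-"
        chrom = f"chr{chrom_i}"
        row, txs, cassette, nxt = _make_gene(rng, gid, sym, chrom, cursor, strand, n_exons, two, cat)
        if nxt > chrom_cap:
            chrom_lens[chrom] = cursor + 500
            chrom_i += 1
            cursor = 1_000
            chrom = f"chr{chrom_i}"
            row, txs, cassette, nxt = _make_gene(rng, gid, sym, chrom, cursor, strand, n_exons, two, cat)
        gene_rows[gid] = row
        for t in txs:
            transcripts[t.transcript_id] = t
        if cassette is not None:
            cassettes[gid] = cassette
        cursor = nxt
    chrom_lens[f"chr{chrom_i}"] = cursor + 500
    genes = pd.DataFrame.from_dict(gene_rows, orient="index")
    genes.index.name = "gene_id"

    # domains on fusion genes: two non-overlapping aa spans with GO labels
    go_pool = [
        ("transcription_regulation", "nucleus", "dna_binding"),
        ("signal_transduction", "cytoplasm", "kinase_activity"),
        ("rna_processing", "nucleus", "rna_binding"),
        ("chromatin_organization", "nucleus", "histone_binding"),
    ]
    dom_rows = []
    for gid, row in genes[genes.category == "fusion"].iterrows():
        t = transcripts[f"{gid}.t1"]
        prot_len = t.cds_length // 3
        third = prot_len // 3
        for d in range(2):
            a = 2 + d * 2 * third
            b = min(a + third - 1, prot_len)
            go = go_pool[int(rng.integers(0, len(go_pool)))]
            dom_rows.append(
                {
                    "gene_id": gid,
                    "domain_id": f"PF{rng.integers(10000, 99999):05d}",
                    "aa_start": a,
                    "aa_end": b,
                    "go_bp": go[0],
                    "go_cc": go[1],
                    "go_mf": go[2],
                }
            )
    domains = pd.DataFrame(dom_rows)

    # ---------------- clinical + latent risk
    n_samples = spec.n_cohorts * spec.patients_per_cohort
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    cohorts = [f"cohort{c + 1:02d}" for c in range(spec.n_cohorts) for _ in range(spec.patients_per_cohort)]
    sex = np.where(rng.random(n_samples) < 0.5, "F", "M")
    tissue = np.where(rng.random(n_samples) < 0.7, "bone_marrow", "peripheral_blood")
    age = np.round(np.clip(rng.lognormal(1.0, 0.9, n_samples), 0.1, 18.0), 1)

    group_names = sorted(spec.fusion_group_freqs)
    probs = [spec.fusion_group_freqs[g] for g in group_names]
    p_none = max(0.0, 1.0 - sum(probs))
    draw = rng.choice(len(group_names) + 1, size=n_samples, p=probs + [p_none])
    group_of = [group_names[d] if d < len(group_names) else None for d in draw]
    risk_p = np.array([RISK_BY_GROUP.get(g, 0.5) for g in group_of])
    high = rng.random(n_samples) < risk_p

    # ---------------- splicing plan
    event_gids = [gid for gid, _, cat, _ in plan if cat == "event"]
    n_planted = int(round(spec.planted_event_fraction * spec.n_events))
    planted_gids = event_gids[:n_planted]
    n_motif = int(round(spec.motif_planting_fraction * n_planted))
    motif_gids = planted_gids[:n_motif]
    mu_low = 0.5 - spec.delta_psi_planted / 2
    mu_high = 0.5 + spec.delta_psi_planted / 2
    base_mu = {gid: float(rng.uniform(0.25, 0.75)) for gid in event_gids[n_planted:]}

    # ---------------- genome sequence + motif insertion
    sequences = {}
    for chrom, ln in chrom_lens.items():
        sequences[chrom] = rng.integers(0, 4, size=ln)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for gid in motif_gids:
        chrom = gene_rows[gid]["chrom"]
        strand = gene_rows[gid]["strand"]
        c_start, c_end = cassettes[gid]
        off = 30
        if strand == "+":
            # donor intron of the cassette exon: motif at [c_end+off, c_end+off+5]
            g0 = c_end + off - 1  # 0-based
            for i, b in enumerate(spec.planted_motif):
                sequences[chrom][g0 + i] = base_idx[b]
        else:
            rc = "".join(comp[b] for b in reversed(spec.planted_motif))
            g_end = c_start - off  # 1-based end of the motif segment
            g0 = g_end - 6  # 0-based start
            for i, b in enumerate(rc):
                sequences[chrom][g0 + i] = base_idx[b]
    lut = np.array(list("ACGT"))
    seq_str = {c: "".join(lut[v]) for c, v in sequences.items()}

    bundle_annotation = AnnotationBundle(
        genes=genes.drop(columns=["category"]).copy(),
        transcripts=transcripts,
        domains=domains,
        sequences=seq_str,
    )
    bundle_annotation.genes["category"] = genes.category  # keep for consumers

    # ---------------- expression (TPM per transcript)
    all_gids = list(genes.index)
    gi = {g: k for k, g in enumerate(all_gids)}
    base_log2 = rng.normal(5.0, 1.5, size=len(all_gids))
    # keep planted-signal genes comfortably expressed so PSI is defined
    for gid, _, cat, _ in plan:
        if cat in ("prognostic", "de_up", "de_down", "event"):
            base_log2[gi[gid]] = rng.normal(6.0, 0.8)
    disp = rng.uniform(0.1, 0.4, size=len(all_gids))
    batch = {f"cohort{c + 1:02d}": rng.normal(0.0, 0.3, size=len(all_gids)) for c in range(spec.n_cohorts)}
    sex_mask = rng.random(len(all_gids)) < 0.05
    sex_eff = np.where(sex_mask, rng.normal(0.0, 0.3, size=len(all_gids)), 0.0)
    tissue_mask = rng.random(len(all_gids)) < 0.05
    tissue_eff = np.where(tissue_mask, rng.normal(0.0, 0.3, size=len(all_gids)), 0.0)

    prog_idx = np.array([gi[gid] for gid, _, cat, _ in plan if cat == "prognostic"])
    de_up_idx = np.array([gi[gid] for gid, _, cat, _ in plan if cat == "de_up"])
    de_down_idx = np.array([gi[gid] for gid, _, cat, _ in plan if cat == "de_down"])

    log2m = np.tile(base_log2[:, None], (1, n_samples))
    for s in range(n_samples):
        log2m[:, s] += batch[cohorts[s]]
        if sex[s] == "M":
            log2m[:, s] += sex_eff
        if tissue[s] == "peripheral_blood":
            log2m[:, s] += tissue_eff
        if high[s]:
            log2m[prog_idx, s] += spec.de_log_fc
        if group_of[s] == "KMT2A-r":
            log2m[de_up_idx, s] += spec.de_log_fc
        if group_of[s] == "ETV6-r":
            log2m[de_down_idx, s] += spec.de_log_fc

    mean = np.power(2.0, log2m)
    nb_n = (1.0 / disp)[:, None]
    nb_p = nb_n / (nb_n + mean)
    gene_abund = rng.negative_binomial(nb_n, nb_p).astype(float)

    # transcript split: PSI for event genes
    tx_ids = sorted(transcripts)
    tx_rows = {}
    psi_real = {}
    for gid in all_gids:
        row = gene_abund[gi[gid]]
        if gid in cassettes:
            if gid in planted_gids:
                mus = np.where(high, mu_high, mu_low)
            else:
                mus = np.full(n_samples, base_mu[gid])
            conc = 50.0
            psis = rng.beta(mus * conc, (1 - mus) * conc)
            psi_real[gid] = psis
            tx_rows[f"{gid}.t1"] = row * psis
            tx_rows[f"{gid}.t2"] = row * (1 - psis)
        else:
            tx_rows[f"{gid}.t1"] = row
    tx_mat = np.vstack([tx_rows[t] for t in tx_ids])
    tpm = pd.DataFrame(
        tx_mat / tx_mat.sum(axis=0, keepdims=True) * 1e6, index=tx_ids, columns=samples
    )

    # ---------------- survival
    gene_tpm_prog = np.vstack(
        [tpm.loc[f"{all_gids[k]}.t1"].to_numpy() for k in prog_idx]
    )
    score = np.log2(gene_tpm_prog + 1).mean(axis=0)
    z = (score - score.mean()) / score.std()
    lam0 = np.log(2) / 2500.0  # per day; z = 0 median EFS of ~2500 days
    lam = lam0 * np.exp(spec.prognostic_log_hazard * z)
    t_event = rng.exponential(1.0 / lam)
    censor = np.full(n_samples, 3000.0)
    extra = rng.random(n_samples) < spec.censoring_rate
    censor[extra] = rng.uniform(0, 1500, size=int(extra.sum()))
    event = (t_event <= censor).astype(int)
    efs = np.round(np.minimum(t_event, censor), 1)

    clinical = pd.DataFrame(
        {
            "cohort": cohorts,
            "sex": sex,
            "tissue": tissue,
            "age_years": age,
            "relapse": event,
            "efs_time_days": efs,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    read_stats = pd.DataFrame(
        {
            "sample_id": samples,
            "mapped_fraction": np.round(rng.uniform(0.55, 0.95, n_samples), 3),
            "mapped_reads": rng.integers(8_000_000, 40_000_000, n_samples),
        }
    )

    # ---------------- fusion calls
    ledger = TruthLedger(
        planted_motif=spec.planted_motif,
        planted_rbp="RBP01",
        hub_gene="SRRM1",
        prognostic_gene_ids=[gid for gid, _, cat, _ in plan if cat == "prognostic"],
        de_gene_ids={
            "KMT2A-r_vs_ETV6-r": {
                "up": [gid for gid, _, cat, _ in plan if cat == "de_up"],
                "down": [gid for gid, _, cat, _ in plan if cat == "de_down"],
            }
        },
        risk_labels={s: ("high" if h else "low") for s, h in zip(samples, high)},
        fusion_group_by_sample={s: g for s, g in zip(samples, group_of)},
        survival_params={
            s: {"hazard": float(l), "time": float(t), "event": int(e)}
            for s, l, t, e in zip(samples, lam, efs, event)
        },
    )
    sym2gid = {row["symbol"]: gid for gid, row in gene_rows.items()}

    def breakpoint_str(sym, frac):
        gid = sym2gid[sym]
        row = gene_rows[gid]
        pos = int(row["start"] + frac * (row["end"] - row["start"]))
        return f"{row['chrom']}:{pos}:{row['strand']}"

    calls = []
    genes_used: dict[str, set] = {s: set() for s in samples}

    def emit(sample, g5, g3, faf_ab=(6.0, 10.0), category="true", fusion_id=None):
        j, sp, wt5, wt3, ffpm = _faf_counts(rng, *faf_ab)
        calls.append(
            {
                "sample_id": sample,
                "cohort_id": clinical.loc[sample, "cohort"],
                "gene5": g5,
                "gene3": g3,
                "left_breakpoint": breakpoint_str(g5, float(rng.uniform(0.3, 0.8))),
                "right_breakpoint": breakpoint_str(g3, float(rng.uniform(0.1, 0.5))),
                "junction_reads": j,
                "spanning_frags": sp,
                "ffpm": ffpm,
                "large_anchor": True,
                "wt5_reads": wt5,
                "wt3_reads": wt3,
            }
        )
        genes_used[sample].update((g5, g3))
        fid = fusion_id or f"{g5}::{g3}"
        if category == "true":
            ledger.true_fusions_by_sample.setdefault(sample, []).append(fid)
        else:
            ledger.artifact_calls_by_class.setdefault(category, []).append([sample, fid])

    # true fusions per group; secondary partner in ~30% of the group's patients
    for gname in group_names:
        info = FUSION_GROUPS[gname]
        members = [s for s, g in zip(samples, group_of) if g == gname]
        n_alt = int(round(0.3 * len(members)))
        # guard: only use the secondary pair when it can reach 5 patients
        if n_alt < 5:
            n_alt = 0
        alt_members = set(members[:n_alt])
        main_members = [s for s in members if s not in alt_members]
        n_recip = int(np.ceil(0.5 * len(main_members))) if info["reciprocal"] else 0
        if n_recip < 5:
            n_recip = 0
        for k, s in enumerate(main_members):
            emit(s, info["hub"], info["partners"][0])
            if k < n_recip:
                emit(s, info["partners"][0], info["hub"])
        for s in sorted(alt_members):
            emit(s, info["hub"], info["partners"][1])

    # per-sample artifact classes
    rates = {**_default_artifact_rates(), **spec.artifact_rates}
    per_sample_pools = {
        "pseudogene": _PSEUDO_PAIRS,
        "paralog": _PARALOG_PAIRS,
        "immunoglobulin": _IG_PAIRS,
    }
    for cls, pool in per_sample_pools.items():
        rate = rates.get(cls, 0.0)
        if rate <= 0:
            continue
        for s in samples:
            k = int(rng.poisson(rate))
            if not k:
                continue
            picks = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
            for p in picks:
                a, b = pool[p]
                if a in genes_used[s] or b in genes_used[s]:
                    continue
                emit(s, a, b, category=cls)
    rate = rates.get("promiscuous", 0.0)
    if rate > 0:
        for s in samples:
            if rng.random() < rate and _PROM_HUB not in genes_used[s]:
                x, y = rng.choice(len(_PROM_PARTNERS), size=2, replace=False)
                emit(s, _PROM_HUB, _PROM_PARTNERS[x], category="promiscuous")
                emit(s, _PROM_HUB, _PROM_PARTNERS[y], category="promiscuous")

    # cohort-structured artifact classes
    def plant_pairwise(cls, pairs, rate, one_cohort=False, faf_ab=(6.0, 10.0), count_range=None):
        total = int(round(rate * n_samples))
        if total < (2 if count_range else 5):
            return
        if count_range:  # low-recurrence: few patients each
            n_pairs = min(len(pairs), max(1, total // 3))
        else:
            n_pairs = min(len(pairs), max(1, total // 8))
        per = max(5, total // n_pairs) if not count_range else None
        for k in range(n_pairs):
            a, b = pairs[k]
            if one_cohort:
                c = f"cohort{(k % spec.n_cohorts) + 1:02d}"
                cand = [s for s in samples if clinical.loc[s, "cohort"] == c]
            else:
                cand = list(samples)
            cand = [s for s in cand if a not in genes_used[s] and b not in genes_used[s]]
            n_take = per if per is not None else int(rng.integers(*count_range))
            n_take = min(n_take, len(cand))
            if one_cohort:
                chosen = [cand[i] for i in rng.choice(len(cand), size=n_take, replace=False)]
            else:
                # interleave cohorts so multi-cohort classes truly span >= 2 projects
                by_cohort: dict[str, list] = {}
                for s in cand:
                    by_cohort.setdefault(str(clinical.loc[s, "cohort"]), []).append(s)
                queues = []
                for c in sorted(by_cohort):
                    lst = by_cohort[c]
                    rng.shuffle(lst)
                    queues.append(lst)
                order = [q[i] for i in range(max(map(len, queues))) for q in queues if i < len(q)]
                chosen = order[:n_take]
            for s in chosen:
                emit(s, a, b, faf_ab=faf_ab, category=cls)

    plant_pairwise("normal_panel", _NORMAL_PAIRS, rates.get("normal_panel", 0.0))
    plant_pairwise("single_project", _SINGLE_PROJECT_PAIRS, rates.get("single_project", 0.0), one_cohort=True)
    plant_pairwise("low_faf", _LOW_FAF_PAIRS, rates.get("low_faf", 0.0), faf_ab=(1.5, 50.0))
    plant_pairwise("low_recurrence", _LOW_REC_PAIRS, rates.get("low_recurrence", 0.0), count_range=(2, 5))

    fusion_calls = pd.DataFrame(
        calls,
        columns=[
            "sample_id", "cohort_id", "gene5", "gene3", "left_breakpoint", "right_breakpoint",
            "junction_reads", "spanning_frags", "ffpm", "large_anchor", "wt5_reads", "wt3_reads",
        ],
    )

    # ---------------- knowledge tables
    known = {}
    for gname, info in FUSION_GROUPS.items():
        for p, c in zip(info["partners"], info["classes"]):
            if c != "novel":
                known[frozenset((info["hub"], p))] = c
    # a couple of extra catalog entries exercising class precedence
    known[frozenset(("GSE1", "SLC7A5"))] = "solid"
    known[frozenset(("CBFA2T3", "PIEZO1"))] = "solid"
    leukemia = set()
    for info in FUSION_GROUPS.values():
        leukemia.add(info["hub"])
        leukemia.update(info["partners"])
    knowledge = KnowledgeTables(
        pseudogenes={a for a, _ in _PSEUDO_PAIRS},
        paralog_pairs={frozenset(p) for p in _PARALOG_PAIRS},
        ig_hb_genes={s for p in _IG_PAIRS for s in p},
        normal_panel_pairs={frozenset(p) for p in _NORMAL_PAIRS},
        known_fusions=known,
        leukemia_genes=leukemia,
    )

    # ---------------- splicing truth (event signatures)
    def se_id(gid):
        c_start, c_end = cassettes[gid]
        exons = transcripts[f"{gid}.t1"].exons
        ci = [k for k, e in enumerate(exons) if e == (c_start, c_end)][0]
        a_end = exons[ci - 1][1]
        b_start = exons[ci + 1][0]
        return se_event_id(gid, gene_rows[gid]["chrom"], a_end, c_start, c_end, b_start, gene_rows[gid]["strand"])

    ledger.event_ids_planted_dpsi = [se_id(g) for g in planted_gids]
    ledger.motif_bearing_event_ids = [se_id(g) for g in motif_gids]

    # ---------------- gene sets
    prog_ids = ledger.prognostic_gene_ids
    third = max(1, len(prog_ids) // 3)
    bg_ids = [gid for gid, _, cat, _ in plan if cat == "background"]
    gene_sets = {
        "MYC_TARGETS": sorted(prog_ids[:third] + bg_ids[:20]),
        "TRANSLATION_GO": sorted(prog_ids[third : 2 * third] + bg_ids[20:40]),
        "SF_RBP": sorted(prog_ids[2 * third :] + bg_ids[40:60]),
    }

    # ---------------- motif DB
    kmers_taken = {spec.planted_motif}
    rbps = {}
    while len(rbps) < 14:
        k = "".join(lut[rng.integers(0, 4, 6)])
        if k in kmers_taken:
            continue
        kmers_taken.add(k)
        rbps[f"RBP{len(rbps) + 2:02d}"] = k
    kmer_map = {"RBP01": {spec.planted_motif}, **{r: {k} for r, k in rbps.items()}}

    def one_hot_pfm(kmer, w=0.85):
        m = np.full((4, len(kmer)), (1 - w) / 3)
        for i, b in enumerate(kmer):
            m[base_idx[b], i] = w
        return m

    motif_db = MotifDB(
        pfms={r: [one_hot_pfm(next(iter(ks)))] for r, ks in kmer_map.items()},
        kmers=kmer_map,
    )

    # ---------------- PPI (symbols)
    gid2sym = {gid: row["symbol"] for gid, row in gene_rows.items()}
    sig_syms = [gid2sym[g] for g in prog_ids]
    edges = []
    for sym in sig_syms[1:7]:  # hub SRRM1 to >= 5 signature genes
        edges.append(("SRRM1", sym, int(rng.integers(200, 700)), int(rng.integers(920, 995))))
    for r in ["RBP01", "RBP02", "RBP03", "RBP04", "RBP05", "RBP06"]:
        edges.append(("SRRM1", r, int(rng.integers(150, 600)), int(rng.integers(910, 990))))
    bg_syms = [gid2sym[g] for g in bg_ids[:40]]
    for k in range(0, min(20, len(bg_syms) - 1), 2):  # decoys failing the filters
        edges.append((bg_syms[k], bg_syms[k + 1], 0, int(rng.integers(920, 990))))
    for k in range(20, min(36, len(bg_syms) - 1), 2):
        edges.append((bg_syms[k], bg_syms[k + 1], int(rng.integers(100, 500)), int(rng.integers(300, 900))))
    ppi = pd.DataFrame(edges, columns=["protein_a", "protein_b", "experimental", "combined"])

    return CohortBundle(
        spec=spec,
        annotation=bundle_annotation,
        fusion_calls=fusion_calls,
        tpm=tpm,
        clinical=clinical,
        read_stats=read_stats,
        knowledge=knowledge,
        gene_sets=gene_sets,
        motif_db=motif_db,
        ppi=ppi,
        ledger=ledger,
    )
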