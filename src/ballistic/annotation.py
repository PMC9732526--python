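"""Gene/transcript annotation container with GTF and FASTA round-trip.

The bundle is the shared substrate for breakpoint derivation, domain
mapping, splicing-event generation and motif-region extraction.
Coordinates are 1-based inclusive genomic throughout; BED exports are
0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["Transcript", "AnnotationBundle"]


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    exons: list[tuple[int, int]]  # 1-based inclusive, sorted by genomic start
    cds_start: int | None = None  # genomic span of the CDS (inclusive)
    cds_end: int | None = None

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if c <= b:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons ({a},{b}) and ({c},{d})"
                )

    @property
    def length(self) -> int:
        return sum(b - a + 1 for a, b in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def cds_exon_pieces(self) -> list[tuple[int, int]]:
        """Exon fragments intersected with the CDS span, genomic order."""
        if self.cds_start is None or self.cds_end is None:
            return []
        pieces = []
        for a, b in self.exons:
            lo, hi = max(a, self.cds_start), min(b, self.cds_end)
            if lo <= hi:
                pieces.append((lo, hi))
        return pieces

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds_exon_pieces())


@dataclass
class AnnotationBundle:
    """Genes, transcripts, protein-domain table and genome sequences."""

    genes: pd.DataFrame  # index gene_id; symbol, chrom, strand, biotype, start, end
    transcripts: dict[str, Transcript]
    domains: pd.DataFrame  # gene_id, domain_id, aa_start, aa_end, go_bp, go_cc, go_mf
    sequences: dict[str, str] = field(default_factory=dict)

    def transcripts_of(self, gene_id: str) -> list[Transcript]:
        return [t for t in self.transcripts.values() if t.gene_id == gene_id]

    def strand(self, gene_id: str) -> str:
        return str(self.genes.loc[gene_id, "strand"])

    def chrom(self, gene_id: str) -> str:
        return str(self.genes.loc[gene_id, "chrom"])

    def symbol_to_gene_id(self) -> dict[str, str]:
        return {str(s): g for g, s in self.genes["symbol"].items()}

    def transcript_lengths(self) -> pd.Series:
        return pd.Series({t.transcript_id: t.length for t in self.transcripts.values()})

    def transcript_gene_map(self) -> pd.Series:
        return pd.Series({t.transcript_id: t.gene_id for t in self.transcripts.values()})

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end] 1-based inclusive, reverse-complemented on '-'."""
        seq = self.sequences[chrom][start - 1 : end]
        if strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    # ------------------------------------------------------------------ I/O

    def write_gtf(self, path: str | Path) -> None:
        rows = []
        for gid, g in self.genes.sort_index().iterrows():
            attrs = (
                f'gene_id "{gid}"; gene_name "{g.symbol}"; gene_biotype "{g.biotype}";'
            )
            rows.append(
                (g.chrom, "ballistic", "gene", g.start, g.end, ".", g.strand, ".", attrs)
            )
            for t in sorted(self.transcripts_of(gid), key=lambda t: t.transcript_id):
                tat = f'gene_id "{gid}"; transcript_id "{t.transcript_id}"; gene_name "{g.symbol}";'
                rows.append(
                    (g.chrom, "ballistic", "transcript", t.span[0], t.span[1], ".", g.strand, ".", tat)
                )
                for a, b in t.exons:
                    rows.append((g.chrom, "ballistic", "exon", a, b, ".", g.strand, ".", tat))
                if t.cds_start is not None:
                    for a, b in t.cds_exon_pieces():
                        rows.append((g.chrom, "ballistic", "CDS", a, b, ".", g.strand, ".", tat))
        with open(path, "w") as fh:
            for r in rows:
                fh.write("\t".join(str(x) for x in r) + "\n")

    @classmethod
    def read_gtf(cls, path: str | Path, domains: pd.DataFrame | None = None) -> "AnnotationBundle":
        import pyranges as pr

        df = pr.read_gtf(str(path)).df
        df["Start"] = df["Start"] + 1  # back to 1-based inclusive
        genes = (
            df[df.Feature == "gene"]
            .assign(
                gene_id=lambda d: d.gene_id,
                symbol=lambda d: d.gene_name,
                chrom=lambda d: d.Chromosome.astype(str),
                strand=lambda d: d.Strand,
                biotype=lambda d: d.get("gene_biotype", "protein_coding"),
                start=lambda d: d.Start,
                end=lambda d: d.End,
            )[["gene_id", "symbol", "chrom", "strand", "biotype", "start", "end"]]
            .set_index("gene_id")
        )
        transcripts: dict[str, Transcript] = {}
        exon_rows = df[df.Feature == "exon"]
        for tid, sub in exon_rows.groupby("transcript_id", sort=True):
            transcripts[tid] = Transcript(
                transcript_id=str(tid),
                gene_id=str(sub.gene_id.iloc[0]),
                exons=list(zip(sub.Start, sub.End)),
            )
        cds_rows = df[df.Feature == "CDS"]
        for tid, sub in cds_rows.groupby("transcript_id", sort=True):
            t = transcripts[str(tid)]
            t.cds_start, t.cds_end = int(sub.Start.min()), int(sub.End.max())
        if domains is None:
            domains = pd.DataFrame(
                columns=["gene_id", "domain_id", "aa_start", "aa_end", "go_bp", "go_cc", "go_mf"]
            )
        return cls(genes=genes, transcripts=transcripts, domains=domains)

    def write_fasta(self, path: str | Path) -> None:
        recs = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in sorted(self.sequences.items())
        ]
        SeqIO.write(recs, str(path), "fasta")

    @staticmethod
    def read_fasta(path: str | Path) -> dict[str, str]:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}

    def write_domains(self, path: str | Path) -> None:
        self.domains.to_csv(path, sep="\t", index=False)
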