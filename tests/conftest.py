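"""Shared fixtures: synthetic cohorts and derived matrices.

Bundles are generated once per session; every expensive derivation
(normalized expression, fusion cascade) is session-cached too.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ballistic.annotation import AnnotationBundle, Transcript
from ballistic.expression_de import logcpm, tmm_normalize, tpm_to_gene_counts
from ballistic.fusion_catalog import run_catalog
from ballistic.synthetic_cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_bundle():
    return generate_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def small_bundle():
    spec = CohortSpec(
        n_cohorts=3, patients_per_cohort=30, n_genes=300, n_events=60, seed=2
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def default_catalog(default_bundle):
    return run_catalog(
        default_bundle.fusion_calls,
        default_bundle.knowledge,
        all_samples=list(default_bundle.clinical.index),
    )


@pytest.fixture(scope="session")
def default_logcpm(default_bundle):
    ann = default_bundle.annotation
    counts = tpm_to_gene_counts(
        default_bundle.tpm,
        ann.transcript_lengths(),
        ann.transcript_gene_map(),
        default_bundle.read_stats.set_index("sample_id").mapped_reads,
    )
    return logcpm(counts, tmm_normalize(counts))


@pytest.fixture(scope="session")
def risk_inputs(default_bundle, default_logcpm):
    """Contrast logFCs, training cohort and labels for the risk cascade."""
    b = default_bundle
    cl = b.clinical
    groups = pd.Series(b.ledger.fusion_group_by_sample)
    train = cl.index[cl.cohort == "cohort01"]
    other = cl.index[cl.cohort != "cohort01"]
    rel = cl.loc[train, "relapse"]
    lfc_rel = default_logcpm.loc[:, train[rel == 1]].mean(axis=1) - default_logcpm.loc[
        :, train[rel == 0]
    ].mean(axis=1)
    km = [s for s in other if groups[s] == "KMT2A-r"]
    ev = [s for s in other if groups[s] == "ETV6-r"]
    lfc_fus = default_logcpm[km].mean(axis=1) - default_logcpm[ev].mean(axis=1)
    return {
        "lfc_relapse": lfc_rel,
        "lfc_fusion": lfc_fus,
        "train": train,
        "relapse": rel,
    }


def _tx(tid, gid, exons, cds=None):
    t = Transcript(tid, gid, exons)
    if cds:
        t.cds_start, t.cds_end = cds
    return t


@pytest.fixture(scope="session")
def toy_annotation():
    """Hand-built annotation: one gene per splicing event type plus a
    minus-strand gene and a single-isoform gene, on a tiny genome."""
    genes = pd.DataFrame(
        [
            # SE: cassette exon 201-250 between 1-100 and 301-400
            ("gSE", "GSE", "chrT", "+", "protein_coding", 1, 400),
            # RI: intron 501-540 retained in one isoform (exons 451-500, 541-600)
            ("gRI", "GRI", "chrT", "+", "protein_coding", 451, 600),
            # A3: shared donor at 700, acceptors 801 vs 821 (overlapping exons)
            ("gA3", "GA3", "chrT", "+", "protein_coding", 651, 900),
            # A5: donors 1050 vs 1070 to shared acceptor 1151
            ("gA5", "GA5", "chrT", "+", "protein_coding", 1001, 1300),
            # MX: exclusive exons 1451-1500 vs 1551-1600 between 1401-1420 and 1651-1700
            ("gMX", "GMX", "chrT", "+", "protein_coding", 1401, 1700),
            # AF: first exons 1801-1850 vs 1901-1950 joined to 2001 acceptor
            ("gAF", "GAF", "chrT", "+", "protein_coding", 1801, 2100),
            # AL: last exons 2301-2350 vs 2401-2450 from donor at 2250
            ("gAL", "GAL", "chrT", "+", "protein_coding", 2201, 2450),
            # minus-strand SE gene
            ("gNEG", "GNEG", "chrT", "-", "protein_coding", 2601, 3000),
            # single isoform
            ("gONE", "GONE", "chrT", "+", "protein_coding", 3101, 3400),
        ],
        columns=["gene_id", "symbol", "chrom", "strand", "biotype", "start", "end"],
    ).set_index("gene_id")
    transcripts = {
        "tSE.1": _tx("tSE.1", "gSE", [(1, 100), (201, 250), (301, 400)], (11, 340)),
        "tSE.2": _tx("tSE.2", "gSE", [(1, 100), (301, 400)]),
        "tRI.1": _tx("tRI.1", "gRI", [(451, 600)]),
        "tRI.2": _tx("tRI.2", "gRI", [(451, 500), (541, 600)]),
        "tA3.1": _tx("tA3.1", "gA3", [(651, 700), (801, 900)]),
        "tA3.2": _tx("tA3.2", "gA3", [(651, 700), (821, 900)]),
        "tA5.1": _tx("tA5.1", "gA5", [(1001, 1050), (1151, 1300)]),
        "tA5.2": _tx("tA5.2", "gA5", [(1001, 1070), (1151, 1300)]),
        "tMX.1": _tx("tMX.1", "gMX", [(1401, 1420), (1451, 1500), (1651, 1700)]),
        "tMX.2": _tx("tMX.2", "gMX", [(1401, 1420), (1551, 1600), (1651, 1700)]),
        "tAF.1": _tx("tAF.1", "gAF", [(1801, 1850), (2001, 2100)]),
        "tAF.2": _tx("tAF.2", "gAF", [(1901, 1950), (2001, 2100)]),
        "tAL.1": _tx("tAL.1", "gAL", [(2201, 2250), (2301, 2350)]),
        "tAL.2": _tx("tAL.2", "gAL", [(2201, 2250), (2401, 2450)]),
        "tNEG.1": _tx("tNEG.1", "gNEG", [(2601, 2700), (2801, 2850), (2901, 3000)], (2611, 2990)),
        "tNEG.2": _tx("tNEG.2", "gNEG", [(2601, 2700), (2901, 3000)]),
        "tONE.1": _tx("tONE.1", "gONE", [(3101, 3200), (3301, 3400)], (3111, 3390)),
    }
    domains = pd.DataFrame(
        columns=["gene_id", "domain_id", "aa_start", "aa_end", "go_bp", "go_cc", "go_mf"]
    )
    rng = np.random.default_rng(7)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3500)])
    return AnnotationBundle(
        genes=genes, transcripts=transcripts, domains=domains, sequences={"chrT": seq}
    )
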