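"""End-to-end pipeline: QC -> fusions -> domains -> expression/DE ->
risk -> splicing -> motifs -> co-occurrence/PPI.

Stages consume the on-disk formats written by the simulator (GTF, FASTA,
TSV, GMT, PFM) and write TSV/JSON outputs per stage under the output
directory, together with a run manifest recording input/output hashes
and the parameter snapshot. A single global seed fans out to per-stage
seeds by a stable derivation so re-runs (and stage re-runs) reproduce
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    annotation as ann_mod,
    cooccurrence_ppi,
    domain_impact,
    expression_de,
    fusion_catalog,
    motif_enrichment,
    risk_signature,
    splicing_events,
    synthetic_cohort,
)

logger = logging.getLogger("ballistic.pipeline")

STAGES = ["qc", "fusions", "domains", "expression", "risk", "splicing", "motifs", "cooccurrence"]

DEFAULT_PARAMS = {
    "min_patients": 5,
    "median_faf_min": 0.1,
    "partner_median_min": 0.01,
    "exclusivity_alpha": 0.05,
    "contrast": "KMT2A-r:ETV6-r",
    "training_cohort": "cohort01",
    "gsea_n_perm": 1000,
    "n_trees": 400,
    "mtry": 4,
    "k_threshold": 0.7,
    "psi_max_missing": 0.10,
    "impute_k": 10,
    "sd_min": 0.1,
    "dpsi_min": 0.2,
    "ds_fdr_max": 0.01,
    "motif_window": 200,
    "motif_n_subsamples": 100,
    "motif_z": 1.5,
    "hub_gene": "SRRM1",
}


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str
    seed: int = 0
    params: dict = field(default_factory=dict)
    stages: list = field(default_factory=lambda: list(STAGES))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def param(self, key):
        return self.params.get(key, DEFAULT_PARAMS[key])

    def validate(self) -> None:
        if not Path(self.input_dir).is_dir():
            raise FileNotFoundError(f"input directory {self.input_dir} does not exist")
        unknown = set(self.params) - set(DEFAULT_PARAMS)
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stage(s): {bad}")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.stages: dict = {}

    def record(self, stage, inputs, outputs, params, seconds, n_warnings):
        self.stages[stage] = {
            "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
            "outputs": {str(p): _sha256(Path(p)) for p in outputs if Path(p).exists()},
            "params": params,
            "seconds": round(seconds, 2),
            "warnings": n_warnings,
        }
        self.path.write_text(json.dumps(self.stages, indent=1, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    config.validate()
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir / "manifest.json")
    state: dict = {}

    for stage in STAGES:
        if stage not in config.stages:
            logger.info("stage %s disabled", stage)
            continue
        runner = globals()[f"_stage_{stage}"]
        t0 = time.time()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                inputs, outputs, params = runner(indir, outdir, config, state)
            except KeyError as exc:
                raise RuntimeError(
                    f"stage {stage}: missing upstream output {exc}; "
                    "enable the producing stage or check its results"
                ) from exc
        manifest.record(stage, inputs, outputs, params, time.time() - t0, len(caught))
        logger.info("stage %s done (%.1fs)", stage, time.time() - t0)
    return manifest.stages


# -------------------------------------------------------------------- stages


def _stage_qc(indir, outdir, config, state):
    stats = pd.read_csv(indir / "read_stats.tsv", sep="\t")
    retained, log = synthetic_cohort.sample_qc(stats)
    d = outdir / "qc"
    d.mkdir(exist_ok=True)
    log.to_csv(d / "sample_qc.tsv", sep="\t", index=False)
    state["retained"] = retained
    state["read_stats"] = stats.set_index("sample_id").loc[retained]
    state["clinical"] = pd.read_csv(indir / "clinical.tsv", sep="\t", index_col="sample_id").loc[retained]
    return [indir / "read_stats.tsv"], [d / "sample_qc.tsv"], {}


def _stage_fusions(indir, outdir, config, state):
    calls = fusion_catalog.parse_fusion_calls(indir / "fusion_calls.tsv")
    calls = calls[calls.sample_id.isin(state["retained"])].reset_index(drop=True)
    knowledge = fusion_catalog.KnowledgeTables.read(indir / "knowledge")
    res = fusion_catalog.run_catalog(
        calls,
        knowledge,
        min_patients=config.param("min_patients"),
        median_faf_min=config.param("median_faf_min"),
        partner_median_min=config.param("partner_median_min"),
        exclusivity_alpha=config.param("exclusivity_alpha"),
        all_samples=state["retained"],
    )
    d = outdir / "fusions"
    d.mkdir(exist_ok=True)
    res.write(d)
    state["catalog"] = res
    # single-group label per sample (exactly one exclusive group)
    pres = res.presence
    n_groups = pres.sum(axis=0)
    labels = pd.Series(index=pres.columns, dtype=object)
    for s in pres.columns:
        if n_groups[s] == 1:
            labels[s] = pres.index[pres[s] == 1][0]
        elif n_groups[s] == 0:
            labels[s] = "none"
        else:
            labels[s] = "multiple"
    state["group_label"] = labels
    outs = [d / "fusion_catalog.tsv", d / "fusion_filter_trail.tsv", d / "fusion_presence_matrix.tsv"]
    return [indir / "fusion_calls.tsv"], outs, {
        "min_patients": config.param("min_patients"),
        "median_faf_min": config.param("median_faf_min"),
    }


def _load_annotation(indir, state):
    if "annotation" not in state:
        domains = pd.read_csv(indir / "domains.tsv", sep="\t")
        bundle = ann_mod.AnnotationBundle.read_gtf(indir / "annotation.gtf", domains=domains)
        bundle.sequences = ann_mod.AnnotationBundle.read_fasta(indir / "genome.fa")
        state["annotation"] = bundle
    return state["annotation"]


def _stage_domains(indir, outdir, config, state):
    bundle = _load_annotation(indir, state)
    cat = state["catalog"]
    table, rollup = domain_impact.analyze_catalog(cat.records, cat.surviving_calls, bundle)
    d = outdir / "domains"
    d.mkdir(exist_ok=True)
    table.to_csv(d / "domain_impact.tsv", sep="\t", index=False)
    rollup.to_csv(d / "go_rollup.tsv", sep="\t", index=False)
    if len(table):
        domain_impact.write_bed(table, bundle, d / "domains.bed")
    return [indir / "annotation.gtf", indir / "domains.tsv"], [d / "domain_impact.tsv", d / "go_rollup.tsv"], {}


def _stage_expression(indir, outdir, config, state):
    bundle = _load_annotation(indir, state)
    tpm = pd.read_csv(indir / "transcript_tpm.tsv", sep="\t", index_col=0)
    tpm = tpm[state["retained"]]
    counts = expression_de.tpm_to_gene_counts(
        tpm,
        bundle.transcript_lengths(),
        bundle.transcript_gene_map(),
        state["read_stats"].mapped_reads,
    )
    factors = expression_de.tmm_normalize(counts)
    lcpm = expression_de.logcpm(counts, factors)
    state["tpm"] = tpm
    state["logcpm"] = lcpm
    d = outdir / "expression"
    d.mkdir(exist_ok=True)
    factors.to_frame().to_csv(d / "tmm_factors.tsv", sep="\t")

    g1, g2 = config.param("contrast").split(":")
    labels = state["group_label"]
    contrast_samples = labels[labels.isin([g1, g2])]
    clin = state["clinical"]
    de = expression_de.fit_de(
        lcpm,
        contrast_samples,
        covariates=clin.loc[contrast_samples.index, ["sex", "cohort", "tissue"]],
    )
    de.to_csv(d / "de.tsv", sep="\t", index=False, float_format="%.6g")
    rnk = de.set_index("gene_id").rank_metric.sort_values(ascending=False)
    rnk.to_csv(d / "de.rnk", sep="\t", header=False, float_format="%.6g")
    sets = expression_de.read_gmt(indir / "gene_sets.gmt")
    gsea = expression_de.preranked_gsea(
        de.set_index("gene_id").rank_metric,
        sets,
        n_perm=config.param("gsea_n_perm"),
        seed=stage_seed(config.seed, "gsea"),
    )
    gsea.to_csv(d / "gsea.tsv", sep="\t", index=False, float_format="%.6g")
    state["de"] = de
    state["gene_sets"] = sets
    return (
        [indir / "transcript_tpm.tsv", indir / "gene_sets.gmt"],
        [d / "de.tsv", d / "de.rnk", d / "gsea.tsv", d / "tmm_factors.tsv"],
        {"contrast": config.param("contrast"), "gsea_n_perm": config.param("gsea_n_perm")},
    )


def _stage_risk(indir, outdir, config, state):
    lcpm = state["logcpm"]
    clin = state["clinical"]
    labels = state["group_label"]
    g1, g2 = config.param("contrast").split(":")
    train = clin.index[clin.cohort == config.param("training_cohort")]
    other = clin.index[clin.cohort != config.param("training_cohort")]
    rel = clin.loc[train, "relapse"]
    lfc_relapse = lcpm.loc[:, train[rel == 1]].mean(axis=1) - lcpm.loc[:, train[rel == 0]].mean(axis=1)
    a = [s for s in other if labels.get(s) == g1]
    bgrp = [s for s in other if labels.get(s) == g2]
    lfc_fusion = lcpm[a].mean(axis=1) - lcpm[bgrp].mean(axis=1)

    candidates = risk_signature.select_candidates(lfc_relapse, lfc_fusion, state["gene_sets"])
    cox = risk_signature.cox_filter(candidates, lcpm[train], clin.loc[train])
    survivors = cox.loc[cox.kept, "gene_id"].tolist()
    var = risk_signature.variability_filter(survivors, lcpm, clin.cohort)
    signature = var.loc[var.kept, "gene_id"].tolist()

    seed = stage_seed(config.seed, "risk")
    loo = risk_signature.train_and_score_loo(
        lcpm.loc[signature, train],
        rel,
        n_trees=config.param("n_trees"),
        mtry=config.param("mtry"),
        threshold=config.param("k_threshold"),
        seed=seed,
    )
    ev = risk_signature.evaluate(
        loo.k_score, rel, clin.loc[train, "efs_time_days"], rel,
        threshold=config.param("k_threshold"),
    )
    model = risk_signature.train_model(
        lcpm.loc[signature, train], rel,
        n_trees=config.param("n_trees"), mtry=config.param("mtry"),
        threshold=config.param("k_threshold"), seed=seed,
    )
    scorecard = risk_signature.apply_model(model, lcpm)
    sweep = risk_signature.threshold_sweep(loo.k_score, rel)

    d = outdir / "risk"
    d.mkdir(exist_ok=True)
    cox.to_csv(d / "cox_filter.tsv", sep="\t", index=False, float_format="%.6g")
    var.to_csv(d / "variability_filter.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame({"gene_id": signature}).to_csv(d / "signature.tsv", sep="\t", index=False)
    loo.to_csv(d / "loo_scorecard.tsv", sep="\t", float_format="%.6g")
    scorecard.to_csv(d / "scorecard.tsv", sep="\t", float_format="%.6g")
    ev["roc"].to_csv(d / "roc.tsv", sep="\t", index=False, float_format="%.6g")
    sweep.to_csv(d / "threshold_sweep.tsv", sep="\t", index=False, float_format="%.6g")
    metrics = {"auc": ev["auc"], "logrank_stat": ev["logrank_stat"], "logrank_p": ev["logrank_p"],
               "n_candidates": len(candidates), "n_signature": len(signature)}
    (d / "metrics.json").write_text(json.dumps(metrics, indent=1, sort_keys=True))
    state["signature"] = signature
    state["scorecard"] = scorecard
    state["risk_metrics"] = metrics
    outs = [d / n for n in ["signature.tsv", "loo_scorecard.tsv", "scorecard.tsv", "roc.tsv",
                            "threshold_sweep.tsv", "metrics.json"]]
    return [], outs, {"n_trees": config.param("n_trees"), "mtry": config.param("mtry"),
                      "k_threshold": config.param("k_threshold")}


def _stage_splicing(indir, outdir, config, state):
    bundle = _load_annotation(indir, state)
    events = splicing_events.generate_events(bundle)
    psi = splicing_events.compute_psi(events, state["tpm"])
    completed = splicing_events.filter_and_impute(
        psi, max_missing=config.param("psi_max_missing"), k=config.param("impute_k")
    )
    risk_class = state["scorecard"].risk_class
    clin = state["clinical"]
    ds = splicing_events.diff_splice(
        completed,
        risk_class,
        covariates=clin[["sex", "cohort", "tissue"]],
        sd_min=config.param("sd_min"),
        dpsi_min=config.param("dpsi_min"),
        fdr_max=config.param("ds_fdr_max"),
    )
    binary = splicing_events.binarize_inclusion(completed)
    event_gene = pd.Series({e.event_id: e.gene_id for e in events})
    corr, frac = splicing_events.psi_expression_correlation(
        completed.loc[completed.index.intersection(ds.loc[ds.significant, "event_id"])],
        state["logcpm"],
        event_gene,
    ) if ds.significant.any() else (pd.DataFrame(), float("nan"))

    d = outdir / "splicing"
    d.mkdir(exist_ok=True)
    splicing_events.events_to_frame(events).to_csv(d / "events.tsv", sep="\t", index=False)
    completed.to_csv(d / "psi.tsv", sep="\t", float_format="%.6g")
    ds.to_csv(d / "diff_splice.tsv", sep="\t", index=False, float_format="%.6g")
    binary.to_csv(d / "psi_binary.tsv", sep="\t")
    if len(corr):
        corr.to_csv(d / "psi_expression_corr.tsv", sep="\t", index=False, float_format="%.6g")
    state["events"] = events
    state["psi_binary"] = binary
    state["ds"] = ds
    state["frac_corr_gt"] = frac
    return [indir / "annotation.gtf"], [d / "events.tsv", d / "psi.tsv", d / "diff_splice.tsv",
                                        d / "psi_binary.tsv"], {
        "sd_min": config.param("sd_min"), "dpsi_min": config.param("dpsi_min")}


def _stage_motifs(indir, outdir, config, state):
    bundle = _load_annotation(indir, state)
    db = motif_enrichment.MotifDB.read(indir / "motifs")
    ds = state["ds"]
    sig = sorted(ds.loc[ds.significant, "event_id"])
    enr = motif_enrichment.run_enrichment(
        state["events"], sig, bundle, db,
        window=config.param("motif_window"),
        n_samples=config.param("motif_n_subsamples"),
        seed=stage_seed(config.seed, "motifs"),
        z_threshold=config.param("motif_z"),
    )
    d = outdir / "motifs"
    d.mkdir(exist_ok=True)
    enr.to_csv(d / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    state["enrichment"] = enr
    return [str(indir / "motifs" / "motifs.pfm")], [d / "enrichment.tsv"], {
        "window": config.param("motif_window")}


def _stage_cooccurrence(indir, outdir, config, state):
    ds = state["ds"]
    sig = sorted(set(ds.loc[ds.significant, "event_id"]) & set(state["psi_binary"].index))
    binary = state["psi_binary"].loc[sig]
    risk_high = (state["scorecard"].risk_class == "high").astype(int)
    groups = state["group_label"].replace({"multiple": None})
    cooc = cooccurrence_ppi.event_risk_cooccurrence(binary, risk_high, groups)

    ppi_raw = pd.read_csv(indir / "ppi_edges.tsv", sep="\t")
    ppi = cooccurrence_ppi.filter_ppi(ppi_raw)
    enr = state.get("enrichment")
    d = outdir / "cooccurrence"
    d.mkdir(exist_ok=True)
    cooc.to_csv(d / "event_risk_cooccurrence.tsv", sep="\t", index=False, float_format="%.6g")
    ppi.to_csv(d / "ppi_filtered.tsv", sep="\t", index=False)
    outs = [d / "event_risk_cooccurrence.tsv", d / "ppi_filtered.tsv"]
    if enr is not None and len(enr):
        bundle = _load_annotation(indir, state)
        gid2sym = bundle.genes.symbol.to_dict()
        sig_syms = [gid2sym.get(g, g) for g in state["signature"]]
        rbps = sorted(enr.loc[enr.enriched, "rbp"].unique())
        if rbps:
            overlap = cooccurrence_ppi.interactor_overlap(
                rbps, sig_syms, config.param("hub_gene"), ppi
            )
            overlap.to_csv(d / "interactor_overlap.tsv", sep="\t", index=False)
            outs.append(d / "interactor_overlap.tsv")
            state["interactors"] = overlap
    else:
        logger.info("motif stage disabled or empty; interactor overlap skipped")
    return [indir / "ppi_edges.tsv"], outs, {"hub_gene": config.param("hub_gene")}
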