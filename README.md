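# ballistic

Multicohort transcriptome analysis for B-cell acute lymphoblastic
leukemia (B-ALL): gene-fusion prioritization by fusion allele frequency,
protein-domain impact of fusions, a fusion-independent gene-expression
signature of relapse risk, PSI-based differential splicing, RNA-binding
protein (RBP) motif enrichment against GC/length-matched controls, and
probabilistic co-occurrence testing — with a synthetic-cohort generator
that plants every signal and records it in a machine-readable truth
ledger, so the whole pipeline can be validated end to end without
controlled-access patient data.

## Who this is for

Computational biologists who analyze pediatric leukemia RNA-seq across
heterogeneous cohorts and need a tested, reusable implementation of the
filtering, scoring and enrichment steps that such studies chain
together — or who want a planted-truth benchmark to validate their own.

## The methods at the core

**Fusion allele frequency (FAF).** For a fusion with junction-spanning
read count F and wild-type reads WT_i over each partner's breakpoint,

    FAF_i = F_i / (F_i + WT_i),   FAF = (FAF_L + FAF_R) / 2,

a proxy for fusion clonality. Candidate calls pass an evidence filter
(junction reads ≥ 1, spanning fragments ≥ 1, FFPM ≥ 0.1, ≥ 25 bases of
anchor on both sides), artifact filters (pseudogene partners, paralogous
pairs, immunoglobulin/hemoglobin pairs, promiscuous genes), recurrence
filters (normal-tissue panel, single-project, < 5 patients; known
leukemia genes bypass all but the patient count), and FAF thresholds
(median FAF > 0.1; lower-partner median ≥ 0.01). Survivors are
classified (ALL > blood > solid > novel), grouped by the most recurrent
partner ("KMT2A-r"), and groups without mutual exclusivity collapse into
"Other".

**Risk signature.** Genes over-expressed (log2FC > 0.5) both in
relapse-vs-non-relapse and in KMT2A-r-vs-ETV6-r, restricted to MYC
targets / translation GO / splicing-factor-RBP sets, filtered by a Cox
proportional-hazards Wald test (p < 0.05, adjusted for age and sex) and
by cross-cohort stability (max cohort-mean logCPM spread ≤ 3). A
400-tree random forest (4 candidate features per split) scores each
sample with a k-score = fraction of trees voting relapse; k ≥ 0.7 is
high-risk. Evaluation is leave-one-out: ROC/AUC, Kaplan–Meier and
log-rank at the 0.7 split.

**Differential splicing.** Splicing events (SE, A3, A5, AF, AL, MX, RI)
are enumerated from annotation; PSI = inclusion TPM / total TPM,
undefined below 1 TPM; events missing in > 10% of samples are dropped
and the rest imputed by k-nearest-neighbour averaging. A linear model on
logit PSI with sex/project/tissue covariates calls significance at
|ΔPSI| > 0.2 and FDR < 0.01.

**Motif enrichment.** 200-nt windows flank each alternative splice
site; 6-mers (exact) and position frequency matrices (log-likelihood
ratio ≥ 80% of maximum) are scanned on the sense strand. Observed
per-motif frequencies are compared with 100 control subsamples matched
on length × GC; enrichment is z > 1.5.

**Co-occurrence.** With fixed marginals m_A, m_B over N samples the
co-occurrence count is hypergeometric; P(≤ j) and P(≥ j) are computed
exactly. The same test drives fusion-group mutual exclusivity and the
association of event inclusion (PSI > 0.5) with high risk inside each
fusion group, and STRING-style PPI edges (experimental > 0,
combined > 900) connect enriched RBPs to the signature around an
SRRM1-like hub.

## Worked example

```bash
ballistic simulate --out /tmp/cohort --seed 1
ballistic run --input /tmp/cohort --out /tmp/results --seed 11
```

The first command writes a 5-cohort, 300-patient synthetic dataset
(GTF + FASTA annotation, STAR-Fusion-style calls, transcript TPM,
clinical table, knowledge tables, motif DB, PPI edges, truth ledger).
The second runs QC → fusions → domains → expression/DE → risk →
splicing → motifs → co-occurrence and prints

```
pipeline finished: 8 stages -> /tmp/results
```

`/tmp/results/risk/metrics.json` then contains (seed-for-seed
reproducible):

```json
{
 "auc": 0.9854910714285714,
 "logrank_p": 3.794465925071352e-16,
 "logrank_stat": 66.34016933636225,
 "n_candidates": 40,
 "n_signature": 40
}
```

i.e. the leave-one-out k-score separates relapse from non-relapse
patients in the training cohort with AUC 0.985 and the 0.7-threshold
split separates the Kaplan–Meier curves at log-rank p ≈ 4e-16 — strong
by design, since the generator plants a 40-gene prognostic program with
a large hazard effect. `/tmp/results/fusions/fusion_catalog.tsv` lists
the surviving fusions with class, group and FAF medians;
`/tmp/results/motifs/enrichment.tsv` shows the planted 6-mer as the top
z-score.

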