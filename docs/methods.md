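# Methods

This note documents the models and procedures implemented in
`ballistic`, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical and design
choices made where the design was genuinely open.

## Fusion cascade

Calls are consumed in a STAR-Fusion v1.4 dialect; wild-type read
support per partner may be given as counts or inverted from per-side
allele frequencies (WT_i = F_i (1 − f_i)/f_i). The cascade is:

1. **Evidence** (per call): junction reads ≥ 1, spanning fragments ≥ 1,
   FFPM ≥ 0.1, large-anchor support. Boundaries are inclusive ("at
   least" semantics).
2. **Artifact block** (per call, order-invariant — each filter is
   evaluated independently on the full input): pseudogene partner;
   paralogous pair (≥ 70%-identity list); both partners
   immunoglobulin/hemoglobin; promiscuity — a gene partnered with more
   than one distinct other gene in the same sample loses all its calls
   there. The exact reciprocal (B::A of A::B) does not count as a second
   partner, since reciprocal fusions co-occur as genuine events;
   known-leukemia genes are exempt.
3. **Recurrence block** (per fusion, ordered gene pair): normal-tissue
   panel; single project; fewer than 5 supporting patients. Fusions
   involving known leukemia-mutated/fused genes bypass the panel,
   single-project and promiscuity filters but never the patient count.
4. **FAF thresholds**: median FAF across supporting patients strictly
   above 0.1, and the lower-FAF partner's median individual FAF at
   least 0.01.

Every call carries a full filter trail (pass/fail/skipped per filter
plus the first failing filter), so each removal is attributable.
Classification matches unordered pairs with precedence
ALL > blood > solid > novel. Group labels use the gene with the larger
supporting-patient total ("<GENE>-r", ties lexicographic). Mutual
exclusivity between groups is tested pairwise with the exact
hypergeometric co-occurrence model (P(≤ observed) < 0.05); groups
exclusive with no partner collapse into "Other". This replaces a
waiting-time model for mutually exclusive alterations with the same
co-occurrence test used elsewhere in the package — one exact,
dependency-free test reused throughout.

## Domain impact

Representative transcript per gene = longest annotated CDS (ties by
transcript id). Exonic caller breakpoints are used verbatim; intronic
ones snap to the last base of the last retained exon (5' partner) or
the first base of the first retained exon (3' partner),
transcription-strand aware. Amino-acid spans map through the CDS
([3(a−1)+1, 3b] in coding coordinates) to genomic interval lists whose
total length is exactly 3 × aa length; the inverse mapping is provided
and round-trips exactly. A domain is *kept* only when all its intervals
lie wholly on the retained side of the breakpoint (breakpoint base
included); any overlap is *lost* — the binary scheme has no
"truncated" class. GO rollups count a domain once per GO label;
unlabeled domains count as "unannotated". Coordinates are 1-based
inclusive internally, 0-based half-open in BED export.

## Expression and differential expression

Transcript TPM → gene counts by length weighting: pseudo-count =
TPM × length, rescaled so each sample's counts sum to its mapped-read
library size, then summed per gene. TMM normalization follows the
standard recipe: reference = sample with upper-quartile closest to the
mean; per sample a precision-weighted mean of M-values after trimming
30% from each tail of M and 5% of A; factors rescaled to geometric mean
1 (cross-checked against edgeR in the test suite). logCPM uses prior
count 0.5 on TMM-scaled library sizes.

The DE model is per-gene OLS on logCPM with group + sex + project +
tissue. Surrogate-variable adjustment is not re-implemented: the known
covariates fully describe the generator's batch structure, and the
project covariate carries the cohort effect. Variance moderation
(on by default) fits a scaled inverse chi-square prior by method of
moments on log sample variances (trigamma inversion for the prior df);
genes with mean logCPM < 0 are pre-filtered; significance is FDR < 0.01
and |log2FC| > 1. The rank metric is r = −log10(p)·log2FC; the
splicing-factor/RBP set is ranked by |r| as it has no expected
direction. Pre-ranked GSEA uses the weighted Kolmogorov–Smirnov running
sum (weight 1; weight 0 available, which is invariant to monotone
metric transforms), a seeded gene-label permutation null (default
1000), NES = ES / mean same-sign |null ES|.

## Risk signature and k-score model

The cascade: log2FC > 0.5 in both contrasts (relapse vs non-relapse in
the training cohort; KMT2A-r vs ETV6-r elsewhere, both as differences
of mean normalized logCPM) ∧ membership in ≥ 1 of the three gene sets →
per-gene Cox PH on event-free survival with standardized expression +
age + sex, Wald p < 0.05 (Efron ties via lifelines; non-converging or
constant genes are excluded with a reason) → cross-cohort stability
(max pairwise cohort-mean logCPM difference ≤ 3).

The ensemble is a random forest: 400 trees, 4 candidate features per
split, bootstrap resampling, seeded. The k-score is the fraction of
trees voting the relapse class — vote fraction rather than probability
averaging, for exact reproducibility. Trees use balanced class weights:
in leave-one-out evaluation the held-out sample shifts its training
fold's class prior against its own class, which biases vote fractions
and drags null (label-permuted) AUC well below 0.5; balancing cancels
that first-order leak so permuted labels score near 0.5 while real
signal is unaffected. Feature selection is performed once on the full
training cohort, not per fold — the model evaluates a fixed signature.
k ≥ 0.7 classifies high-risk; a threshold sweep
(sensitivity/specificity/accuracy on a 0.05 grid) is always reported.
Scoring new samples tolerates ≤ 10% missing signature genes by
training-mean imputation. Instead of a regularized-log variant of the
model, a test asserts rank-stability of k-scores under monotone
per-gene renormalization.

## Differential splicing

Events are enumerated by pairwise transcript comparison per gene with
coordinate signatures (cassette exon, alternative 3'/5' splice sites
requiring the alternative exons to overlap, alternative first/last
exons requiring non-overlapping terminal exons joined to a shared
exon, mutually exclusive exons, retained introns), deduplicated, with
membership recomputed against all isoforms. PSI = inclusion TPM / total
TPM, undefined below 1 TPM total. Events missing in > 10% of samples
are dropped; remaining gaps are imputed by k-nearest-neighbour
averaging over events (k = 10, Euclidean on co-observed samples,
unweighted — the convention of the standard nearest-neighbour
imputation tool). The model is OLS on logit PSI (clipping ε = 0.01; a
test verifies significance calls are stable at ε = 0.001) with the same
covariates as DE and no variance moderation, so with no covariates it
reduces to the classical two-sample t-test. The SD ≥ 0.1 pre-filter
uses the pooled SD over the compared samples (per-group available via
argument). ΔPSI is the difference of group means on the natural scale,
computed after imputation (the model consumes the completed matrix);
significance requires |ΔPSI| > 0.2 ∧ FDR < 0.01. Binarized inclusion
is PSI > 0.5 (strict).

## Motif enrichment

Windows of 200 nt (configurable) on the exonic and intronic side of
each alternative splice site, sense strand only (RBP motifs act on
pre-mRNA), truncated with a flag at contig ends. 6-mer hits are exact
substring matches; PFM hits score log-likelihood ratio against the
region's 0-order composition (pseudocount 0.01) at ≥ 80% of the maximum
attainable score. The observed statistic per motif × region class is
the fraction of signal events with ≥ 1 hit — event-level, robust to
repeat expansions and consistent with events being the resampling unit.
Controls: 100 subsamples of the non-significant event pool, each of
signal size, stratified over 4 × 4 length × GC quantile bins of the
signal set (nearest-bin fallback when a stratum is short), without
replacement within a subsample, seeded. z = (observed − control mean) /
control SD; SD = 0 yields z = 0 when the observation equals the
constant and an infinite flag otherwise; enrichment is z > 1.5.

A calibration caveat documented deliberately: because the control SD
estimates only the subsampling spread, z is asymptotically standard
normal under an exchangeable null, so |z| ≤ 1.5 holds for about 87% of
null motifs in the continuous limit; the share rises above 90% when
expected hit counts per class are small (≈ 1) and the pool is much
larger than the signal set. Enrichment runs with small signal sets
against large pools are therefore the best-calibrated regime.

## Co-occurrence and PPI

Conditioned on both marginals the co-occurrence count is
hypergeometric; P(≤ j) and P(≥ j) are exact sums. Calls: positive if
P(≥ j) < 0.05, negative (mutually exclusive) if P(≤ j) < 0.05. The
original species-co-occurrence package's "expected < 1" exclusion rule
is off by default and available via argument. Event-vs-risk tests run
within each fusion group (groups with < 5 samples or without both risk
classes are skipped) with BH correction across events within a group —
the multiple-testing scheme chosen here, as no correction was
prescribed for this analysis. PPI edges keep experimental > 0 and
combined > 900 (0–1000 scale); the interactor report lists, per
enriched-motif RBP, hub adjacency, signature interactors and dual-role
membership.

## Synthetic cohorts and the truth ledger

The generator emulates, jointly: multi-cohort batch structure (additive
log2 offsets, SD 0.3), sex/tissue effects on 5% of genes, negative
binomial expression (log-normal gene means, dispersion U(0.1, 0.4)),
fusion groups with canonical hub–partner pairs, reciprocal-pair
co-occurrence and mutual exclusivity by construction, eight artifact
classes each engineered to fail exactly its designated filter (so
filter trails have an unambiguous oracle), two-isoform cassette-exon
genes whose PSI is beta-distributed (concentration 50) around
stratum-dependent means, exponential survival with log-hazard linear in
the standardized planted-gene score, a 6-mer planted in the donor-side
intronic flank of selected events, and a PPI graph wiring an SRRM1-like
hub RBP to the signature and to motif RBPs. Every planted fact is
recorded in the truth ledger, which round-trips losslessly through
JSON.

Default study conditions: 5 cohorts × 60 patients; 600 genes of which
40 prognostic, 60 contrast-DE and 200 two-isoform event genes (30%
with planted ΔPSI = 0.3, 60% of those motif-bearing); planted log2 fold
change 1.5; prognostic log hazard 4.0 per SD of the planted-gene score
with baseline median EFS ≈ 2500 days and uniform extra censoring at
rate 0.25. The hazard coupling is deliberately strong — the planted
program should be recoverable nearly deterministically, because the
package's correctness claims concern the machinery (selection, Cox
filtering, forest scoring), not the clinical effect size; with weaker
coupling the leave-one-out AUC is bounded by the per-stratum event
rates rather than by any property of the code. Effect sizes and rates
were fixed once by forward simulation so that the planted signals are
recoverable at the documented bounds, and are not tuned thereafter.
The motif-enrichment validation uses a dedicated configuration (1000
event genes, 2% planted) for the calibration reasons above.

What the generator does **not** emulate: read-level data (FASTQ/BAM),
realistic genome sequence or gene structure (i.i.d. uniform
nucleotides, compact exon/intron sizes), isoform diversity beyond two
isoforms, overdispersed or correlated gene–gene structure, treatment
effects, or fusion breakpoint sequence context. Passing tests therefore
demonstrate that the pipeline's statistics and bookkeeping are correct
under their stated models — not that the thresholds would perform
identically on real patient cohorts.

## Numerical choices and degenerate inputs

- FAF_i defined 0 when F_i + WT_i = 0; FAF invariant to swapping
  partners together with their counts.
- QC boundaries inclusive (mapped fraction ≥ 0.25, mapped reads ≥ 5M),
  with a per-sample exclusion log; median-FAF strict (> 0.1) vs partner
  median inclusive (≥ 0.01), following the respective wordings.
- BH correction implemented once repo-wide (wrapping the standard
  step-up; NaN p-values propagate).
- The PSI complement identity (inclusion + exclusion fractions = 1)
  holds to one ulp of the two divisions; tests assert ≤ 1e-12.
- Cox fits: lifelines defaults (Efron ties); non-convergence excludes
  the gene with a recorded reason rather than failing the cascade.
- Random forests: seeded, single-threaded, vote fractions over
  `estimators_` — bit-reproducible across runs on the same platform.
- Pipeline seeds: a single global seed fans out per stage via SHA-256
  (< 2^31), so stages can be re-run in isolation reproducibly; the run
  manifest records input/output SHA-256 hashes, parameter snapshots and
  warning counts per stage.

## Problem sizes used in validation

Tests and the acceptance script run on the default cohort (300
samples), a 3 × 30 small cohort for I/O and orchestration checks, the
1000-event configuration for motif calibration, and dedicated
simulations for Cox power (n = 130, ~50% events, 50 replicates) and
splicing calibration (2000 null events at n = 50/50) — sizes chosen so
each check measures what it claims with adequate power while the whole
suite stays quick on a single CPU.

## Known limitations

- Artifact classes are mutually exclusive by construction in the
  generator; real calls can fail several filters at once, where the
  trail records all failures but "removed_by" reports the first in
  cascade order.
- The exclusivity grouping tests pairwise exclusivity only; no
  higher-order (set-wise) exclusion model is implemented.
- GSEA FDR uses same-sign permutation pooling per set; cross-set FDR is
  the BH of permutation p-values rather than the NES-matched scheme of
  the original tool.
- The motif z statistic is mildly anti-conservative by construction
  (see above); interpret borderline z ≈ 1.5 calls accordingly.
- `apply_model` assumes the new matrix shares the training
  normalization recipe; it checks gene coverage, not distributional
  drift.
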