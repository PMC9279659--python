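# Methods

## Problem setting

Somatic single nucleotide variants called from tumor RNA-seq against a
patient-matched normal WES sample are heavily contaminated by RNA-specific
artifacts: A-to-I editing (seen as A>G, or G>A on the opposite strand for
C-to-U), reverse-transcription errors, and misalignment around splice
junctions. The package assumes calling itself has been done by a
haplotype-based somatic caller (Mutect2 + FilterMutectCalls + a functional
annotator); its inputs are the caller's VCF, DNA mutation tables, editing
site lists and interval files. Everything downstream of calling —
filtering, truth construction, classification, and RNA–DNA integration —
is implemented here.

## Multi-filtering

Four rules, applied in a fixed order with per-step accounting:

1. **Targeted-coding-region restriction.** Poly-T-enriched RNA-seq reads
   only mature mRNA, and DNA truth labels only exist inside the WES
   capture, so candidates are restricted to the intersection of the exon
   intervals and the WES target intervals. BED inputs are 0-based
   half-open; variant positions are 1-based, converted internally.
2. **Multiallelic removal.** Loci presenting three or more allele types
   (REF plus two or more ALTs) are removed as likely misalignment. Because
   VCF dialects differ, pre-split lines are grouped by (chrom, pos, ref)
   first: the allele count is a locus property, not a line property.
3. **RNA-editing sites.** Any candidate whose (chrom, pos) lies in the
   union of the two editing-site lists is removed. Matching is positional,
   not allele-aware, because editing databases report strand-ambiguous
   sites.
4. **Immunoglobulin / HLA genes.** Records annotated to genes with
   IGH/IGK/IGL prefixes are removed (noisy alignment in rearranged
   loci), as are records with an `HLA-` gene prefix *on chromosome 6*
   (dense germline variation); an explicit chr6 interval file may be
   supplied instead of gene symbols. The exact immunoglobulin inventory is
   configurable; the prefix rule is the documented default.

All four predicates are record-local (determined by position, locus allele
set, or gene symbol), so the final kept set is independent of step order;
order only affects which step a removal is attributed to. The fixed order
puts restriction first because it is the cheapest and the only rule with a
data-dependence on two resources. Filtering is idempotent, and records
lacking gene annotation are kept with a warning rather than silently
dropped.

## Truth labels

Candidates are keyed by (case, chrom, pos, ref, alt) and joined against
two DNA evidence sources: a gold-standard consensus set (GDC-style MAF
union of multiple callers) and a self-called rescue set that recovers
mutations the consensus pipeline dropped. In gold → TP; rescue-only →
AMBIGUOUS; neither → TN. AMBIGUOUS records have real but weaker DNA
evidence; they are excluded from both training and testing (the
conservative reading — they are neither clean positives nor clean
negatives) but are retained in the audit table. The train/test split is
9:1, stratified on the label so the ~1:8 TP:TN imbalance is preserved in
both subsets; stratification is a design choice, the ratio is the
framework's stated condition.

## Feature schema

Forty named features in three categories:

* **variant level (10):** TLOD, ECNT, STRANDQ, ROQ, SEQQ, GERMQ, CONTQ,
  POPAF, NALOD, NLOD;
* **genotype level (17):** AF_tumor, AD_ref/alt_tumor, DP_tumor,
  AF_normal, AD_ref/alt_normal, DP_normal, MBQ_ref/alt, MMQ_ref/alt,
  MPOS, F1R2/F2R1 alt counts, MFRL_ref/alt;
* **annotation level (13):** the 12 one-hot substitution indicators (A>C …
  T>G; exactly one is 1 per record) and an integer-coded variant
  classification (missense = 1, nonsense = 2, …, unknown → other = 0).

The full inventory used in the original study is not public; this schema
is a reconstruction anchored on the features the model is known to rank
(STRANDQ, AF_tumor, TLOD, ROQ, ECNT, the substitution indicators) and to
drop (A>C, A>T, MMQ_alt), embedded in the standard FilterMutectCalls field
set. It is overridable by passing any name subset.

Imputation: absent Phred-like qualities and depths impute to 0; absent
POPAF imputes to a ceiling of 6 ("not observed in the population",
matching the caller's cap). AF_tumor falls back to ad_alt/(ad_ref+ad_alt)
when the caller's AF field is missing. The imputation mask is retained for
audit; absence in the VCF is represented as absence (`None`), never as a
silent zero.

## Classifier

A random forest with `class_weight="balanced"` (weights inversely
proportional to class frequency, so the minority TP class weighs ~8× the
majority at 1:8 imbalance). Feature selection is RFECV: one least
important feature removed per iteration, 10-fold stratified CV, F1
scoring. Hyperparameters come from an exhaustive cross-validated grid
search (default grid: max_depth {5, 10, 20, ∞} × min_samples_split
{2, 5, 10} × min_samples_leaf {1, 2, 5} × max_features {sqrt, log2}),
best mean F1, ties broken toward the earlier grid point. All randomness
flows through a single seed recorded in the model bundle; predictions are
bit-reproducible for a fixed seed.

Decision rule: positive iff predicted probability ≥ threshold, default
0.5; the boundary case is positive.

### Metrics

The six report metrics follow the framework's printed formulas, two of
which are nonstandard and deliberately preserved: FNR = FN/(FN+TN) and
TNR = TN/(FN+TN) (the textbook FNR would divide by FN+TP). A 0/0 metric is
reported as undefined, never as 0. PR-AUC uses the step-interpolation
(average precision) rule — no linear interpolation between PR points,
which would be optimistic under heavy imbalance. Gini feature importances
are normalized to sum to one.

## RNA–DNA integration

* **Tri-partition:** overlap = RNA ∩ DNA keys, RNA-only = RNA \ DNA,
  DNA-only = DNA \ RNA; the RNA parts are further split by predicted
  class. The four RNA sub-parts always reassemble the candidate set.
* **Gold-standard P–R:** precision = overlap⁺/(overlap⁺ + RNA-only⁺),
  recall = overlap⁺/(overlap⁺ + overlap⁻) — identical to precision/recall
  of the equivalent confusion matrix with overlap⁺ = TP, RNA-only⁺ = FP,
  overlap⁻ = FN. Per-case medians exclude (and count) cases with zero
  predicted positives.
* **Expression ratios:** expression ratio = |overlap| / (|overlap| +
  |DNA-only|); the positive-only variant (|overlap⁺| in the numerator) is
  also emitted since either reading is defensible — the all-overlap form
  is the default. Selective-expression ratio = fraction of DNA-only
  mutations whose force-called RNA *reference* depth strictly exceeds 10:
  the locus is transcribed, the mutant allele is silent.
* **Enrichment:** odds ratio by cross-product (a·d)/(b·c); significance by
  Pearson chi-squared, df = 1, no continuity correction — the uncorrected
  form keeps the test consistent with the plain cross-product OR. A zero
  cell leaves the OR undefined unless the optional Haldane (+0.5)
  correction is enabled; expected cells < 5 trigger a validity warning.
* **Allele-specific expression:** 2×2 Pearson chi-squared on
  [[rna_ref, rna_alt], [dna_ref, dna_alt]], ASE at p < 0.01, direction by
  comparing RNA vs DNA alt fractions. The heterozygosity gate is both DNA
  allelic depths ≥ 2 and RNA total depth ≥ 10 — the thresholds are
  configurable since only the gate itself, not its depths, is prescribed.
* **Fold change:** TPM tumor/normal; ≥ 2 up, ≤ 1/2 down (closed
  thresholds), zero normal TPM → infinite marker, excluded from summaries.
* **Group comparison:** two-sided independent-samples t-test,
  equal-variance form by default (Welch by flag); two zero-variance groups
  with equal means report p = 1.

## Synthetic cohort generator

The generator emulates the structure of a TCGA-like training cohort at
desk scale; it draws *features*, not reads, because the classifier
consumes features — read-level simulation would add cost without
exercising any additional code path.

Genome model: 22 chromosomes × 200 tiles of 10 kb; each tile has an exon
(offsets 2000–4000) and a WES target (2500–4500). Record positions,
planted editing sites and off-target positions are drawn from disjoint
offset zones of the tile, which makes every record's filter fate
deterministic and collision-free: off-target records fall in exon-minus-
target; editing artifacts sit on sites emitted to the REDIportal-/DARNED-
style lists (whose union covers all planted sites, plus decoys);
immunoglobulin/HLA artifacts occupy reserved chr14/chr6 tiles with IG/HLA
gene symbols; multiallelic artifacts carry two ALTs.

Default study conditions (all configurable, chosen once):

* 30 cases × (64 expressed true mutations + ~1,564 artifacts) ≈ 49k
  candidates; artifact count is derived so the post-filter TP:TN label
  ratio is 1:8, the stated training imbalance.
* Artifact composition: 55% editing-site, 5% multiallelic, 5% IG/HLA, 5%
  off-target — 70% removable by the filter rules, matching the reported
  ~70% artifact reduction — and 30% feature-distribution negatives that
  only the model can reject.
* 5% of true mutations appear only in the rescue table (AMBIGUOUS) and 3%
  in neither (RNA-rescued; they become mislabeled TNs, as in real data).
* Expression probability 0.30 (reported per-cohort medians 0.26–0.35): the
  unexpressed remainder of each case's DNA mutations forms the DNA-only
  part, with force-called RNA reference depths high (> 10) for 15% of
  them, matching the reported selective-expression medians (0.12–0.15).
* 25% of expressed mutations carry a planted ASE shift of +0.35–0.50 in
  RNA allele fraction (downward for 10% of them), sized to be detectable
  by the 2×2 chi-squared at typical depths (RNA ~50×, DNA ~80×); the
  reported ASE prevalence is ~24.8% with ~90% mutant-over-expression.
* Per-class feature distributions are clipped location-scale families that
  overlap on every axis (e.g. TLOD 28±12 vs 12±8, STRANDQ 38±16 vs 18±12,
  POPAF 5.4±0.7 vs 4.3±1.3); substitution spectra are somatic-like for TP
  (C>A-rich) and editing-like for TN (A>G/G>A-rich). The separation was
  chosen to emulate the discrimination difficulty of the real cohorts
  (held-out PR-AUC ≈ 0.94–0.96) rather than a trivially separable task.
  Depths are negative-binomial (overdispersed), allele fractions
  beta-distributed, alt depths binomial given depth and fraction.

Everything is driven by one `numpy` generator seed: the same seed yields
byte-identical output files.

### What the generator does *not* emulate

Read-level error processes, mapping ambiguity, germline contamination
structure, inter-gene expression correlation, copy-number and purity
effects, and the long tail of annotation categories. Passing tests
therefore demonstrate that the machinery is correct and that the model
recovers planted structure under realistic imbalance and overlap — not
that the trained model would transfer to real tumors.

## Desk-scale fitting choices

RFECV and the grid search run on a stratified subsample of the training
set (cap 5,000 rows; selection forest 30 trees, grid forest 100 trees,
final forest 300 trees; end-to-end default grid max_depth {10, ∞} ×
min_samples_leaf {1, 2}). These caps keep a full cohort run at a few
minutes on one CPU while leaving the procedures themselves unchanged; all
are settings on `PipelineSettings`.

## Known limitations

* The 40-name schema is a reconstruction (see above); models trained on it
  are not interchangeable with models trained on the original inventory.
* Editing-site matching is positional only; a true somatic mutation at a
  database editing position is filtered.
* The heterozygosity gate uses depth heuristics when genotype calls are
  absent.
* The printed LUSC therapeutic-enrichment odds ratio (13.34) is not the
  cross-product of its printed contingency cells (which give ≈ 13.24);
  the package reproduces the BLCA and GBM ratios exactly and leaves the
  LUSC discrepancy documented rather than resolved.
* Chi-squared p-values printed alongside the published odds ratios do not
  re-derive from the printed cells under either the corrected or
  uncorrected statistic; significance ordering does.
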