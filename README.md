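# rnassnv

Post-calling identification of somatic single nucleotide variants (SSNVs)
from tumor bulk RNA-seq paired with normal whole-exome sequencing (WES).

Calling somatic mutations directly from RNA-seq is attractive — it surfaces
the *expressed* mutations that actually reach the transcriptome, and can
rescue low-VAF mutations that WES misses — but it is plagued by
RNA-specific false positives: A-to-I and C-to-U editing, reverse
transcription errors, and misalignment near splice junctions. This package
implements the post-calling half of that problem for users who already have
Mutect2/FilterMutectCalls-style candidate calls: it filters, labels,
classifies and then interprets RNA SSNV candidates against DNA evidence. It
is aimed at cancer genomics analysts working with paired tumor RNA-seq /
normal WES cohorts (TCGA-style data), and at methods developers who need a
fully synthetic, ground-truthed test bed for RNA somatic calling pipelines.

## What it does

1. **Multi-filtering** — removes multiallelic loci (three or more allele
   types), known RNA-editing sites (union of REDIportal- and DARNED-style
   lists), immunoglobulin-gene and chr6 HLA-gene records, and restricts
   candidates to targeted coding regions (exons ∩ WES capture targets),
   with per-step accounting.
2. **Truth labeling** — joins candidates on (case, chrom, pos, ref, alt)
   against a gold-standard DNA somatic mutation set (GDC-style consensus
   MAF) and a self-called rescue set: in gold → TP, rescue-only →
   AMBIGUOUS (excluded from training), neither → TN.
3. **Classification** — a weighted random forest over ~40 named features at
   variant level (TLOD, ECNT, STRANDQ, ROQ, SEQQ, GERMQ, CONTQ, POPAF, …),
   genotype level (AF, allelic depths, depths, median base/mapping
   qualities, …) and annotation level (12 one-hot substitution indicators
   plus variant classification). Class weights are inverse class
   frequencies (the TP:TN imbalance is ~1:8); features are selected by
   RFECV (10-fold, F1, one feature per iteration) and hyperparameters by
   cross-validated grid search.
4. **Evaluation** — the framework's metric conventions:

   ```
   Precision = TP/(TP+FP)      Recall = TP/(TP+FN)      F1 = 2PR/(P+R)
   FPR = FP/(FP+TN)            FNR = FN/(FN+TN)         TNR = TN/(FN+TN)
   ```

   (note the FN+TN denominators of FNR/TNR), plus PR-AUC by the step
   (average-precision) rule.
5. **RNA–DNA integration** — tri-partition into RNA–DNA overlap, RNA-only
   and DNA-only parts (the RNA parts split by predicted class),
   gold-standard precision/recall (P = overlap⁺/(overlap⁺ + RNA-only⁺),
   R = overlap⁺/(overlap⁺ + overlap⁻)), per-case medians, VAF =
   alt/(ref+alt), expression ratio = |overlap| / (|overlap| + |DNA-only|),
   selective-expression ratio (force-called RNA reference depth > 10 among
   DNA-only), enrichment odds ratios with Pearson chi-squared (no
   continuity correction), allele-specific expression by 2×2 chi-squared on
   RNA vs DNA allelic depths at p < 0.01, and TPM fold-change classes
   (≥ 2 up, ≤ 1/2 down).
6. **Synthetic fixtures** — a deterministic generator emitting per-case
   tumor/normal VCFs, gold/rescue MAF-like tables, editing-site lists in
   both dialects, exon/target BEDs and per-record ground truth, with
   planted editing artifacts, multiallelic records, IG/HLA records,
   off-target records, class-separated feature distributions and a full
   expression/ASE model.

## Worked example

```python
from rnassnv.classifier import ConfusionMatrix, compute_metrics

cm = ConfusionMatrix(tp=4165, fp=566, fn=546, tn=41129)
print(compute_metrics(cm).rounded(3))
```

```
MetricsReport(precision=0.88, recall=0.884, f1=0.882, fpr=0.014,
              fnr=0.013, tnr=0.987, pr_auc=None)
```

A classifier keeping 4,165 of 4,711 true somatic mutations while letting
through 566 of 41,695 artifacts is 88.0% precise and 88.4% sensitive; only
1.4% of artifacts survive.

Filtering one simulated case:

```python
import pandas as pd
from rnassnv.synthetic_fixtures import small_config, simulate_dataset
from rnassnv.pipeline import load_filter_resources
from rnassnv.io_formats import read_vcf_records
from rnassnv.multifilter import apply_multifilter

bundle = simulate_dataset(small_config(), "fixtures/")
records = read_vcf_records(bundle.vcf_paths["CASE0000"], case_id="CASE0000")
kept, report = apply_multifilter(records, load_filter_resources(bundle))
print(pd.DataFrame(report.to_rows()).to_string(index=False))
```

```
              name  n_input  n_removed  n_kept
target_restriction      610         29     581
      multiallelic      581         29     552
     editing_sites      552        322     230
            ig_hla      230         29     201
```

Of 610 candidates, 409 (~70% of the planted artifacts) are removed by the
four rules — mostly known editing sites — and none of the planted true
somatic mutations is lost; the 201 survivors move on to labeling and the
random forest.

The same flow is available from the shell:

```
rnassnv simulate --out fixtures/ --seed 3 --cases 1
rnassnv filter --vcf fixtures/CASE0000.vcf \
    --editing-sites fixtures/editing_rediportal.tsv \
    --darned-sites fixtures/editing_darned.tsv \
    --exons fixtures/exons.bed --targets fixtures/targets.bed \
    --out kept.vcf --report report.tsv
rnassnv run --workdir work/ --seed 0        # full synthetic cohort
```

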