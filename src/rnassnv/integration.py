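"""RNA-DNA integrative statistics.

Given predicted RNA somatic SNVs and a DNA mutation set, candidates split
into three parts: RNA-DNA overlap (expressed, DNA-backed mutations),
RNA-only (no DNA evidence — mostly artifacts plus RNA-rescued calls) and
DNA-only (DNA mutations not observed in RNA). Each RNA part further splits
by the model's positive/negative call. On top of the partition sit the
gold-standard precision/recall, per-case medians, variant allele fractions,
expression ratios, enrichment odds ratios (chi-squared), allele-specific
expression tests on RNA vs DNA allelic depths, TPM fold-change classes and
group score comparisons (two-sided t-test).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MutKey = tuple  # (case_id, chrom, pos, ref, alt)

MUTANT_OVER, MUTANT_UNDER = "MUTANT_OVER", "MUTANT_UNDER"
UP, DOWN, NEUTRAL, INFINITE = "UP", "DOWN", "NEUTRAL", "INFINITE"


@dataclass
class TriPartition:
    """RNA-DNA overlap / RNA-only (each split by predicted class) + DNA-only."""

    overlap_pos: set = field(default_factory=set)
    overlap_neg: set = field(default_factory=set)
    rna_only_pos: set = field(default_factory=set)
    rna_only_neg: set = field(default_factory=set)
    dna_only: set = field(default_factory=set)

    @property
    def n_rna_total(self) -> int:
        return (len(self.overlap_pos) + len(self.overlap_neg)
                + len(self.rna_only_pos) + len(self.rna_only_neg))


def partition_rna_dna(
    predictions: Iterable[tuple[MutKey, bool]],
    dna_keys: Iterable[MutKey],
) -> TriPartition:
    """Split predicted RNA candidates against a DNA mutation key set."""
    dna = set(dna_keys)
    part = TriPartition()
    rna_keys = set()
    for key, positive in predictions:
        rna_keys.add(key)
        if key in dna:
            (part.overlap_pos if positive else part.overlap_neg).add(key)
        else:
            (part.rna_only_pos if positive else part.rna_only_neg).add(key)
    part.dna_only = dna - rna_keys
    return part


def precision_recall_from_parts(
    n_overlap_pos: int, n_overlap_neg: int, n_rna_only_pos: int,
) -> tuple[Optional[float], Optional[float]]:
    """Gold-standard P-R from part sizes: overlap_pos is TP, rna_only_pos FP,
    overlap_neg FN."""
    p_den = n_overlap_pos + n_rna_only_pos
    r_den = n_overlap_pos + n_overlap_neg
    precision = None if p_den == 0 else n_overlap_pos / p_den
    recall = None if r_den == 0 else n_overlap_pos / r_den
    return precision, recall


def gold_standard_pr(part: TriPartition) -> tuple[Optional[float], Optional[float]]:
    return precision_recall_from_parts(
        len(part.overlap_pos), len(part.overlap_neg), len(part.rna_only_pos),
    )


@dataclass
class PerCaseMetrics:
    table: pd.DataFrame                  # case, precision, recall
    median_precision: Optional[float]
    median_recall: Optional[float]
    n_excluded_precision: int            # cases with zero predicted positives


def per_case_metrics(parts: Mapping[str, TriPartition]) -> PerCaseMetrics:
    """Gold-standard P-R per case; summaries are medians across cases."""
    rows = []
    n_excluded = 0
    for case in sorted(parts):
        precision, recall = gold_standard_pr(parts[case])
        if precision is None:
            n_excluded += 1
        rows.append({"case": case, "precision": precision, "recall": recall})
    table = pd.DataFrame(rows, columns=["case", "precision", "recall"])
    precs = table["precision"].dropna()
    recs = table["recall"].dropna()
    return PerCaseMetrics(
        table=table,
        median_precision=None if precs.empty else float(precs.median()),
        median_recall=None if recs.empty else float(recs.median()),
        n_excluded_precision=n_excluded,
    )


def compute_vaf(ad_ref: int, ad_alt: int) -> Optional[float]:
    """Variant allele fraction: alt-supporting reads over total reads."""
    total = ad_ref + ad_alt
    return None if total == 0 else ad_alt / total


@dataclass
class ExpressionRatios:
    expression_ratio: Optional[float]
    selective_expression_ratio: Optional[float]
    expression_ratio_positive_only: Optional[float]


def expression_ratios(
    part: TriPartition,
    dna_only_rna_ref_depth: Mapping[MutKey, float],
    ref_depth_threshold: float = 10,
) -> ExpressionRatios:
    """Expression and selective-expression ratios for one case.

    expression_ratio = expressed DNA mutations / all DNA mutations, where
    the overlap part counts as expressed. The selective-expression ratio is
    the fraction of DNA-only mutations whose force-called RNA reference
    depth strictly exceeds the threshold: the locus is transcribed but the
    mutant allele is silent.
    """
    n_overlap = len(part.overlap_pos) + len(part.overlap_neg)
    n_dna_only = len(part.dna_only)
    total = n_overlap + n_dna_only
    expr = None if total == 0 else n_overlap / total
    expr_pos = None if (len(part.overlap_pos) + n_dna_only) == 0 else \
        len(part.overlap_pos) / (len(part.overlap_pos) + n_dna_only)
    if n_dna_only == 0:
        selective = None
    else:
        n_high = sum(
            1 for key in part.dna_only
            if dna_only_rna_ref_depth.get(key, 0) > ref_depth_threshold
        )
        selective = n_high / n_dna_only
    return ExpressionRatios(expr, selective, expr_pos)


@dataclass
class OrTestResult:
    odds_ratio: Optional[float]
    chi2: float
    p_value: float
    low_expected: bool          # any expected cell < 5 (chi-squared caveat)


def contingency_or_test(
    a: int, b: int, c: int, d: int, haldane: bool = False,
) -> OrTestResult:
    """Odds ratio (cross-product) and Pearson chi-squared p (df=1, no
    continuity correction) for a 2x2 table [[a, b], [c, d]].

    A zero cell leaves the OR undefined unless ``haldane=True`` adds 0.5
    to every cell for the OR only.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("contingency cells must be non-negative")
    table = np.array([[a, b], [c, d]], dtype=float)
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    low_expected = bool((expected < 5).any())
    if low_expected:
        warnings.warn("chi-squared approximation doubtful: expected cell < 5")
    if 0 in (a, b, c, d):
        if haldane:
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            odds = None
    else:
        odds = (a * d) / (b * c)
    return OrTestResult(odds_ratio=odds, chi2=float(chi2), p_value=float(p),
                        low_expected=low_expected)


@dataclass
class AseResult:
    rna_ad: tuple[int, int]
    dna_ad: tuple[int, int]
    chi2: Optional[float]
    p_value: Optional[float]
    is_ase: bool
    direction: Optional[str]
    reason: Optional[str] = None


def passes_het_gate(
    dna_ad: tuple[int, int],
    rna_ad: tuple[int, int],
    min_dna_ad: int = 2,
    min_rna_depth: int = 10,
) -> bool:
    """Heterozygosity/informativeness gate applied before the ASE test."""
    return (min(dna_ad) >= min_dna_ad and sum(rna_ad) >= min_rna_depth)


def ase_test(
    rna_ad: tuple[int, int],
    dna_ad: tuple[int, int],
    alpha: float = 0.01,
) -> AseResult:
    """Allele-specific expression: 2x2 chi-squared on RNA vs DNA allelic depths.

    The table is [[rna_ref, rna_alt], [dna_ref, dna_alt]]; ASE is called at
    p < alpha; direction compares the RNA alt fraction with the DNA one.
    """
    rna_ref, rna_alt = rna_ad
    dna_ref, dna_alt = dna_ad
    table = np.array([[rna_ref, rna_alt], [dna_ref, dna_alt]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return AseResult(rna_ad, dna_ad, None, None, False, None,
                         reason="zero margin; chi-squared undefined")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    rna_frac = rna_alt / (rna_ref + rna_alt)
    dna_frac = dna_alt / (dna_ref + dna_alt)
    return AseResult(
        rna_ad=rna_ad, dna_ad=dna_ad, chi2=float(chi2), p_value=float(p),
        is_ase=bool(p < alpha),
        direction=MUTANT_OVER if rna_frac > dna_frac else MUTANT_UNDER,
    )


@dataclass
class FoldChange:
    fc: float
    label: str


def fold_change_class(tpm_tumor: float, tpm_normal: float) -> FoldChange:
    """Tumor/normal TPM fold change: >= 2 up, <= 1/2 down, else neutral.

    A zero normal TPM yields an INFINITE marker; such genes are excluded
    from fold-change summaries.
    """
    if tpm_normal == 0:
        return FoldChange(math.inf, INFINITE)
    fc = tpm_tumor / tpm_normal
    if fc >= 2:
        return FoldChange(fc, UP)
    if fc <= 0.5:
        return FoldChange(fc, DOWN)
    return FoldChange(fc, NEUTRAL)


def group_score_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sided independent-samples t-test between two score groups."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if np.isnan(t):  # zero variance in both groups
        return (0.0, 1.0) if np.isclose(a.mean(), b.mean()) else (math.inf, 0.0)
    return float(t), float(p)
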