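"""Multi-filtering of RNA somatic SNV candidates.

Four rules remove known artifact classes before any model sees the data:

* restriction to targeted coding regions (exon ∩ WES-target intervals) —
  poly-T mRNA enrichment means only mature-mRNA exons are sequenced, and
  truth labels only exist inside the WES capture;
* multiallelic loci (three or more allele types) — typically misalignment;
* known RNA-editing sites (REDIportal/DARNED union) — A-to-I and C-to-U
  editing is the dominant false-positive source in RNA variant calling;
* immunoglobulin genes and HLA genes on chromosome 6 — noisy alignment and
  dense germline variation.

Every rule is a record-local predicate, so the final kept set does not
depend on step order; the order only attributes removals in the report.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .io_formats import ConfigurationError, IntervalSet, SiteSet, VariantRecord

DEFAULT_IG_PREFIXES = ("IGH", "IGK", "IGL")
DEFAULT_HLA_PREFIX = "HLA-"
DEFAULT_HLA_CHROM = "chr6"

#: fixed application order (restriction first, then record-level rules)
STEP_ORDER = ("target_restriction", "multiallelic", "editing_sites", "ig_hla")


@dataclass
class FilterStep:
    name: str
    n_input: int
    n_removed: int
    n_kept: int

    def __post_init__(self) -> None:
        if self.n_input != self.n_removed + self.n_kept:
            raise ValueError(f"{self.name}: input != removed + kept")


@dataclass
class FilterReport:
    """Ordered per-step accounting; each step's input is the previous kept."""

    steps: list[FilterStep] = field(default_factory=list)

    def add(self, name: str, n_input: int, n_removed: int) -> None:
        step = FilterStep(name, n_input, n_removed, n_input - n_removed)
        if self.steps and step.n_input != self.steps[-1].n_kept:
            raise ValueError(f"{name}: input {step.n_input} != previous kept {self.steps[-1].n_kept}")
        self.steps.append(step)

    @property
    def n_input(self) -> int:
        return self.steps[0].n_input if self.steps else 0

    @property
    def n_kept(self) -> int:
        return self.steps[-1].n_kept if self.steps else 0

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_kept

    def to_rows(self) -> list[dict]:
        return [vars(s).copy() for s in self.steps]


def filter_multiallelic(records: Sequence[VariantRecord]) -> tuple[list, list]:
    """Remove loci presenting three or more allele types.

    Works for both the joint dialect (several ALTs on one line) and the
    pre-split dialect (one ALT per line): lines are grouped by
    (chrom, pos, ref) and the distinct allele count is a locus property.
    """
    alleles: dict[tuple, set] = defaultdict(set)
    for rec in records:
        key = (rec.chrom, rec.pos, rec.ref)
        alleles[key].add(rec.ref)
        alleles[key].update(rec.alts)
    kept, removed = [], []
    for rec in records:
        if len(alleles[(rec.chrom, rec.pos, rec.ref)]) >= 3:
            removed.append(rec)
        else:
            kept.append(rec)
    return kept, removed


def filter_against_sites(records: Sequence[VariantRecord], sites: SiteSet) -> tuple[list, list]:
    """Remove records whose (chrom, pos) lies in the editing-site set."""
    kept, removed = [], []
    for rec in records:
        ((removed if (rec.chrom, rec.pos) in sites else kept)).append(rec)
    return kept, removed


def filter_by_gene_region(
    records: Sequence[VariantRecord],
    ig_prefixes: Sequence[str] = DEFAULT_IG_PREFIXES,
    hla_prefix: str = DEFAULT_HLA_PREFIX,
    hla_chrom: str = DEFAULT_HLA_CHROM,
    hla_intervals: Optional[IntervalSet] = None,
) -> tuple[list, list]:
    """Remove immunoglobulin-gene records and HLA records on chromosome 6.

    Matching is on the annotated gene symbol (IGH/IGK/IGL prefixes; ``HLA-``
    prefix restricted to chr6), optionally extended with explicit chr6
    intervals. Unannotated records are kept with a warning.
    """
    kept, removed = [], []
    n_unannotated = 0
    for rec in records:
        gene = rec.annotations.get("gene")
        if gene is None:
            n_unannotated += 1
        hit = False
        if gene is not None:
            if any(gene.startswith(p) for p in ig_prefixes):
                hit = True
            elif gene.startswith(hla_prefix) and rec.chrom == hla_chrom:
                hit = True
        if not hit and hla_intervals is not None and rec.chrom == hla_chrom:
            hit = hla_intervals.contains_point(rec.chrom, rec.pos)
        (removed if hit else kept).append(rec)
    if n_unannotated:
        warnings.warn(f"{n_unannotated} records lack gene annotation; kept")
    return kept, removed


def restrict_to_targets(
    records: Sequence[VariantRecord],
    exons: IntervalSet,
    wes_targets: IntervalSet,
) -> tuple[list, list]:
    """Keep only records inside both the exon set and the WES target set."""
    kept, removed = [], []
    for rec in records:
        inside = exons.contains_point(rec.chrom, rec.pos) and \
            wes_targets.contains_point(rec.chrom, rec.pos)
        (kept if inside else removed).append(rec)
    return kept, removed


@dataclass
class MultiFilterConfig:
    """Resources and switches for :func:`apply_multifilter`."""

    editing_sites: Optional[SiteSet] = None
    exons: Optional[IntervalSet] = None
    wes_targets: Optional[IntervalSet] = None
    ig_prefixes: Sequence[str] = DEFAULT_IG_PREFIXES
    hla_prefix: str = DEFAULT_HLA_PREFIX
    hla_chrom: str = DEFAULT_HLA_CHROM
    hla_intervals: Optional[IntervalSet] = None
    enable_target_restriction: bool = True
    enable_multiallelic: bool = True
    enable_editing: bool = True
    enable_ig_hla: bool = True


def apply_multifilter(
    records: Sequence[VariantRecord],
    config: MultiFilterConfig,
) -> tuple[list[VariantRecord], FilterReport]:
    """Apply the full multi-filtering strategy with per-step accounting."""
    if config.enable_target_restriction and (config.exons is None or config.wes_targets is None):
        raise ConfigurationError("target restriction enabled but exon/WES-target intervals missing")
    if config.enable_editing and config.editing_sites is None:
        raise ConfigurationError("editing-site filtering enabled but site set missing")

    report = FilterReport()
    current = list(records)

    if config.enable_target_restriction:
        current, removed = restrict_to_targets(current, config.exons, config.wes_targets)
    else:
        removed = []
    report.add("target_restriction", len(current) + len(removed), len(removed))

    if config.enable_multiallelic:
        current, removed = filter_multiallelic(current)
    else:
        removed = []
    report.add("multiallelic", len(current) + len(removed), len(removed))

    if config.enable_editing:
        current, removed = filter_against_sites(current, config.editing_sites)
    else:
        removed = []
    report.add("editing_sites", len(current) + len(removed), len(removed))

    if config.enable_ig_hla:
        current, removed = filter_by_gene_region(
            current, config.ig_prefixes, config.hla_prefix,
            config.hla_chrom, config.hla_intervals,
        )
    else:
        removed = []
    report.add("ig_hla", len(current) + len(removed), len(removed))

    return current, report
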