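"""Readers and writers for the external formats the framework touches.

All coordinates are normalized on read: chromosome names are ``chr``-prefixed
and positions are 1-based for point-like objects (variants, editing sites),
while genomic intervals keep the BED convention (0-based half-open).

The variant entry point is a Mutect2/FilterMutectCalls-style VCF with one
tumor and one normal sample column; DNA somatic mutations arrive as MAF-like
tab-separated tables; RNA-editing sites as REDIportal- or DARNED-style TSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam
from intervaltree import IntervalTree

BASES = frozenset("ACGT")

#: site-level (INFO) quality fields carried through feature extraction
SITE_QUAL_FIELDS = (
    "TLOD", "ECNT", "STRANDQ", "ROQ", "SEQQ", "GERMQ", "CONTQ",
    "POPAF", "NALOD", "NLOD", "MFRL_ref", "MFRL_alt",
)


class FormatError(ValueError):
    """Malformed input file."""


class ConfigurationError(ValueError):
    """Missing or inconsistent reader/writer configuration."""


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name to the GRCh38 ``chr``-prefixed convention."""
    name = str(name).strip()
    if name in ("MT", "chrMT"):
        return "chrM"
    if not name.startswith("chr"):
        return "chr" + name
    return name


def is_snv(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and ref in BASES and alt in BASES


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SampleMetrics:
    """Per-sample genotype metrics for one variant call.

    Median base/mapping qualities and median read position are emitted by
    Mutect2 at site level but are modeled here as tumor genotype metrics,
    matching how the downstream feature schema consumes them. ``None`` means
    the caller did not emit the field (absent, not zero).
    """

    ad_ref: Optional[int] = None
    ad_alt: Optional[int] = None
    af: Optional[float] = None
    depth: Optional[int] = None
    mbq_ref: Optional[float] = None
    mbq_alt: Optional[float] = None
    mmq_ref: Optional[float] = None
    mmq_alt: Optional[float] = None
    mpos: Optional[float] = None
    f1r2_alt: Optional[int] = None
    f2r1_alt: Optional[int] = None


@dataclass
class VariantRecord:
    """One RNA somatic SNV candidate (possibly multiallelic at this stage)."""

    chrom: str
    pos: int
    ref: str
    alts: list[str]
    filters: set[str] = field(default_factory=set)
    site_quals: dict[str, float] = field(default_factory=dict)
    tumor_gt: SampleMetrics = field(default_factory=SampleMetrics)
    normal_gt: SampleMetrics = field(default_factory=SampleMetrics)
    annotations: dict[str, str] = field(default_factory=dict)
    case_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.alts:
            raise ValueError("alts must be nonempty")

    @property
    def alt(self) -> str:
        """Primary (first) alternate allele."""
        return self.alts[0]

    def key(self) -> tuple:
        """(case, chrom, pos, ref, alt) identity used for DNA-evidence joins."""
        return (self.case_id, self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class DnaMutation:
    """One DNA somatic SNV from a gold-standard or self-called table."""

    case_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    ad_ref: Optional[int] = None
    ad_alt: Optional[int] = None
    source: str = "GOLD"

    def key(self) -> tuple:
        return (self.case_id, self.chrom, self.pos, self.ref, self.alt)


class IntervalSet:
    """A set of genomic intervals (BED convention: 0-based half-open).

    Point queries take 1-based positions, which is the coordinate system of
    variant records; the conversion happens internally.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for chrom, start, end in intervals:
            self.add(chrom, start, end)

    def add(self, chrom: str, start: int, end: int) -> None:
        if start >= end:
            raise FormatError(f"interval start >= end: {chrom}:{start}-{end}")
        self._trees.setdefault(normalize_chrom(chrom), IntervalTree()).addi(start, end)
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def contains_point(self, chrom: str, pos_1based: int) -> bool:
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return False
        return bool(tree[pos_1based - 1])

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self._trees):
            for iv in sorted(self._trees[chrom]):
                out.append((chrom, iv.begin, iv.end))
        return out

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Interval intersection (used for 'exons AND WES targets' restriction)."""
        result = IntervalSet()
        for chrom, start, end in self.intervals():
            tree = other._trees.get(chrom)
            if tree is None:
                continue
            for hit in tree.overlap(start, end):
                result.add(chrom, max(start, hit.begin), min(end, hit.end))
        return result


@dataclass(frozen=True)
class SiteSet:
    """Exact (chrom, 1-based pos) membership set of RNA-editing sites."""

    sites: frozenset[tuple[str, int]]
    provenance: str = "UNION"

    def __contains__(self, chrom_pos: tuple[str, int]) -> bool:
        chrom, pos = chrom_pos
        return (normalize_chrom(chrom), int(pos)) in self.sites

    def __len__(self) -> int:
        return len(self.sites)

    def union(self, other: "SiteSet") -> "SiteSet":
        return SiteSet(self.sites | other.sites, provenance="UNION")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _info_scalar(info, key, allele_index=0):
    """Fetch an INFO value; per-allele tuples yield the requested allele."""
    if key not in info:
        return None
    val = info[key]
    if isinstance(val, tuple):
        if len(val) <= allele_index or val[allele_index] is None:
            return None
        return float(val[allele_index])
    if val is None:
        return None
    return float(val)


def _detect_sample_roles(header) -> tuple[Optional[str], Optional[str]]:
    tumor = normal = None
    for rec in header.records:
        text = str(rec).strip()
        if text.startswith("##tumor_sample="):
            tumor = text.split("=", 1)[1]
        elif text.startswith("##normal_sample="):
            normal = text.split("=", 1)[1]
    return tumor, normal


def read_vcf_records(
    path: str | Path,
    tumor_sample: Optional[str] = None,
    normal_sample: Optional[str] = None,
    case_id: Optional[str] = None,
) -> list[VariantRecord]:
    """Read a Mutect2-style VCF into :class:`VariantRecord` objects.

    Tumor/normal sample columns are identified from ``##tumor_sample`` /
    ``##normal_sample`` header lines unless given explicitly. Multiallelic
    lines are kept intact; per-sample metrics refer to the primary ALT.
    Missing quality fields stay absent (``None``), never zero.
    """
    path = Path(path)
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        header_tumor, header_normal = _detect_sample_roles(vcf.header)
        tumor = tumor_sample or header_tumor
        normal = normal_sample or header_normal
        samples = list(vcf.header.samples)
        if tumor is None or normal is None:
            raise ConfigurationError(
                f"{path}: tumor/normal sample designation missing; supply "
                "tumor_sample/normal_sample or ##tumor_sample/##normal_sample "
                "header lines"
            )
        if tumor not in samples or normal not in samples:
            raise ConfigurationError(
                f"{path}: samples {tumor!r}/{normal!r} not among VCF samples {samples}"
            )
        line_no = 0
        try:
            for rec in vcf:
                line_no += 1
                records.append(_variant_from_pysam(rec, tumor, normal, case_id))
        except (ValueError, OSError) as exc:
            raise FormatError(f"{path}: malformed VCF near data line {line_no + 1}: {exc}") from exc
    return records


def _sample_metrics(sample, site_mbq=None, site_mmq=None, site_mpos=None) -> SampleMetrics:
    ad = sample.get("AD")
    af = sample.get("AF")
    f1r2 = sample.get("F1R2")
    f2r1 = sample.get("F2R1")
    if isinstance(af, tuple):
        af = af[0] if af and af[0] is not None else None
    return SampleMetrics(
        ad_ref=None if ad is None or ad[0] is None else int(ad[0]),
        ad_alt=None if ad is None or len(ad) < 2 or ad[1] is None else int(ad[1]),
        af=None if af is None else float(af),
        depth=None if sample.get("DP") is None else int(sample["DP"]),
        mbq_ref=None if site_mbq is None else site_mbq[0],
        mbq_alt=None if site_mbq is None else site_mbq[1],
        mmq_ref=None if site_mmq is None else site_mmq[0],
        mmq_alt=None if site_mmq is None else site_mmq[1],
        mpos=site_mpos,
        f1r2_alt=None if f1r2 is None or len(f1r2) < 2 or f1r2[1] is None else int(f1r2[1]),
        f2r1_alt=None if f2r1 is None or len(f2r1) < 2 or f2r1[1] is None else int(f2r1[1]),
    )


def _ref_alt_pair(info, key):
    if key not in info:
        return None
    val = info[key]
    if not isinstance(val, tuple):
        return (float(val), float(val))
    vals = [None if v is None else float(v) for v in val]
    if len(vals) == 1:
        return (vals[0], vals[0])
    return (vals[0], vals[1])


def _variant_from_pysam(rec, tumor: str, normal: str, case_id) -> VariantRecord:
    info = rec.info
    site_quals: dict[str, float] = {}
    for key in ("TLOD", "ECNT", "STRANDQ", "ROQ", "SEQQ", "GERMQ", "CONTQ",
                "POPAF", "NALOD", "NLOD"):
        val = _info_scalar(info, key)
        if val is not None:
            site_quals[key] = val
    mfrl = _ref_alt_pair(info, "MFRL")
    if mfrl is not None:
        if mfrl[0] is not None:
            site_quals["MFRL_ref"] = mfrl[0]
        if mfrl[1] is not None:
            site_quals["MFRL_alt"] = mfrl[1]
    mbq = _ref_alt_pair(info, "MBQ")
    mmq = _ref_alt_pair(info, "MMQ")
    mpos = _info_scalar(info, "MPOS")

    annotations: dict[str, str] = {}
    if "GENE" in info:
        annotations["gene"] = str(info["GENE"])
    if "VC" in info:
        annotations["variant_classification"] = str(info["VC"])

    return VariantRecord(
        chrom=normalize_chrom(rec.chrom),
        pos=int(rec.pos),
        ref=str(rec.ref),
        alts=[str(a) for a in (rec.alts or ())],
        filters=set(rec.filter.keys()),
        site_quals=site_quals,
        tumor_gt=_sample_metrics(rec.samples[tumor], mbq, mmq, mpos),
        normal_gt=_sample_metrics(rec.samples[normal]),
        annotations=annotations,
        case_id=case_id,
    )


_VCF_HEADER_LINES = [
    '##INFO=<ID=TLOD,Number=A,Type=Float,Description="Log odds of variant existing vs artifact">',
    '##INFO=<ID=ECNT,Number=1,Type=Integer,Description="Number of events in this haplotype">',
    '##INFO=<ID=STRANDQ,Number=1,Type=Integer,Description="Phred-scaled strand bias quality">',
    '##INFO=<ID=ROQ,Number=1,Type=Integer,Description="Phred-scaled read orientation quality">',
    '##INFO=<ID=SEQQ,Number=1,Type=Integer,Description="Phred-scaled sequencing error quality">',
    '##INFO=<ID=GERMQ,Number=1,Type=Integer,Description="Phred-scaled germline quality">',
    '##INFO=<ID=CONTQ,Number=1,Type=Integer,Description="Phred-scaled contamination quality">',
    '##INFO=<ID=POPAF,Number=A,Type=Float,Description="Negative log10 population allele frequency">',
    '##INFO=<ID=NALOD,Number=A,Type=Float,Description="Negative log odds of artifact in normal">',
    '##INFO=<ID=NLOD,Number=A,Type=Float,Description="Normal log odds of no variant">',
    '##INFO=<ID=MBQ,Number=R,Type=Integer,Description="Median base quality per allele">',
    '##INFO=<ID=MMQ,Number=R,Type=Integer,Description="Median mapping quality per allele">',
    '##INFO=<ID=MPOS,Number=A,Type=Integer,Description="Median distance from end of read">',
    '##INFO=<ID=MFRL,Number=R,Type=Integer,Description="Median fragment length per allele">',
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Annotated gene symbol">',
    '##INFO=<ID=VC,Number=1,Type=String,Description="Variant classification">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=F1R2,Number=R,Type=Integer,Description="F1R2 read counts per allele">',
    '##FORMAT=<ID=F2R1,Number=R,Type=Integer,Description="F2R1 read counts per allele">',
]


def write_vcf_records(
    records: Sequence[VariantRecord],
    path: str | Path,
    contig_lengths: Mapping[str, int],
    tumor_sample: str = "TUMOR",
    normal_sample: str = "NORMAL",
) -> None:
    """Write records as an uncompressed Mutect2-style VCF (round-trip safe)."""
    header = pysam.VariantHeader()
    for chrom, length in contig_lengths.items():
        header.contigs.add(normalize_chrom(chrom), length=length)
    for line in _VCF_HEADER_LINES:
        header.add_line(line)
    header.add_line(f"##tumor_sample={tumor_sample}")
    header.add_line(f"##normal_sample={normal_sample}")
    header.add_sample(tumor_sample)
    header.add_sample(normal_sample)

    def chrom_order(chrom: str) -> int:
        return list(header.contigs).index(chrom)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in sorted(records, key=lambda r: (chrom_order(r.chrom), r.pos)):
            vr = out.new_record(
                contig=rec.chrom, start=rec.pos - 1,
                alleles=tuple([rec.ref] + list(rec.alts)),
            )
            vr.filter.add("PASS" if not rec.filters else sorted(rec.filters)[0])
            info = vr.info
            sq = rec.site_quals
            for key in ("ECNT", "STRANDQ", "ROQ", "SEQQ", "GERMQ", "CONTQ"):
                if key in sq:
                    info[key] = int(round(sq[key]))
            for key in ("TLOD", "POPAF", "NALOD", "NLOD"):
                if key in sq:
                    info[key] = tuple([round(float(sq[key]), 2)] * len(rec.alts))
            t = rec.tumor_gt
            if t.mbq_ref is not None:
                info["MBQ"] = tuple([int(round(t.mbq_ref))] +
                                    [int(round(t.mbq_alt))] * len(rec.alts))
            if t.mmq_ref is not None:
                info["MMQ"] = tuple([int(round(t.mmq_ref))] +
                                    [int(round(t.mmq_alt))] * len(rec.alts))
            if t.mpos is not None:
                info["MPOS"] = tuple([int(round(t.mpos))] * len(rec.alts))
            if "MFRL_ref" in sq:
                info["MFRL"] = tuple([int(round(sq["MFRL_ref"]))] +
                                     [int(round(sq["MFRL_alt"]))] * len(rec.alts))
            if "gene" in rec.annotations:
                info["GENE"] = rec.annotations["gene"]
            if "variant_classification" in rec.annotations:
                info["VC"] = rec.annotations["variant_classification"]

            for name, gt in ((tumor_sample, rec.tumor_gt), (normal_sample, rec.normal_gt)):
                sample = vr.samples[name]
                sample["GT"] = (0, 1)
                if gt.ad_ref is not None:
                    sample["AD"] = tuple([gt.ad_ref] + [gt.ad_alt or 0] * len(rec.alts))
                if gt.af is not None:
                    sample["AF"] = tuple([round(float(gt.af), 4)] * len(rec.alts))
                if gt.depth is not None:
                    sample["DP"] = gt.depth
                if gt.f1r2_alt is not None:
                    sample["F1R2"] = tuple([0] + [gt.f1r2_alt] * len(rec.alts))
                if gt.f2r1_alt is not None:
                    sample["F2R1"] = tuple([0] + [gt.f2r1_alt] * len(rec.alts))
            out.write(vr)


# ---------------------------------------------------------------------------
# MAF-like DNA mutation tables
# ---------------------------------------------------------------------------

#: default column names follow the GDC MAF dialect
MAF_COLUMNS = {
    "case": "Tumor_Sample_Barcode",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
    "ad_ref": "t_ref_count",
    "ad_alt": "t_alt_count",
}


def read_dna_mutation_table(
    path: str | Path,
    source: str = "GOLD",
    column_map: Optional[Mapping[str, str]] = None,
    return_stats: bool = False,
):
    """Read a MAF-like TSV of DNA somatic mutations.

    Rows are deduplicated on (case, chrom, pos, ref, alt); non-SNV rows are
    excluded (the framework is SNV-scoped). With ``return_stats=True`` the
    exclusion/duplication counts are returned alongside the mutation list.
    """
    cols = dict(MAF_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for role in ("case", "chrom", "pos", "ref", "alt"):
        if cols[role] not in df.columns:
            raise FormatError(f"{path}: missing required column {cols[role]!r}")

    muts: list[DnaMutation] = []
    seen: set[tuple] = set()
    n_dup = n_non_snv = 0
    for row in df.to_dict(orient="records"):
        ref, alt = row[cols["ref"]], row[cols["alt"]]
        if not is_snv(str(ref), str(alt)):
            n_non_snv += 1
            continue
        mut = DnaMutation(
            case_id=str(row[cols["case"]]),
            chrom=normalize_chrom(row[cols["chrom"]]),
            pos=int(row[cols["pos"]]),
            ref=str(ref),
            alt=str(alt),
            ad_ref=_opt_int(row.get(cols["ad_ref"])),
            ad_alt=_opt_int(row.get(cols["ad_alt"])),
            source=source,
        )
        if mut.key() in seen:
            n_dup += 1
            continue
        seen.add(mut.key())
        muts.append(mut)
    if n_dup:
        warnings.warn(f"{path}: removed {n_dup} duplicate mutation rows")
    if return_stats:
        return muts, {"n_duplicates": n_dup, "n_non_snv": n_non_snv}
    return muts


def _opt_int(val):
    if val is None or (isinstance(val, float) and pd.isna(val)) or val == "" or pd.isna(val):
        return None
    return int(float(val))


def write_dna_mutation_table(muts: Sequence[DnaMutation], path: str | Path) -> None:
    """Write mutations as a GDC-dialect MAF-like TSV."""
    rows = [{
        MAF_COLUMNS["case"]: m.case_id,
        MAF_COLUMNS["chrom"]: m.chrom,
        MAF_COLUMNS["pos"]: m.pos,
        MAF_COLUMNS["ref"]: m.ref,
        MAF_COLUMNS["alt"]: m.alt,
        MAF_COLUMNS["ad_ref"]: "" if m.ad_ref is None else m.ad_ref,
        MAF_COLUMNS["ad_alt"]: "" if m.ad_alt is None else m.ad_alt,
    } for m in muts]
    pd.DataFrame(rows, columns=list(MAF_COLUMNS.values())).to_csv(path, sep="\t", index=False)


def union_dna_mutations(*sets: Iterable[DnaMutation]) -> list[DnaMutation]:
    """Key-level union of mutation tables (first occurrence wins)."""
    seen: set[tuple] = set()
    out: list[DnaMutation] = []
    for muts in sets:
        for m in muts:
            if m.key() not in seen:
                seen.add(m.key())
                out.append(m)
    return out


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_interval_set(path: str | Path) -> IntervalSet:
    """Read a BED3+ file (0-based half-open) into an :class:`IntervalSet`."""
    result = IntervalSet()
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{i}: expected >=3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise FormatError(f"{path}:{i}: start >= end ({start} >= {end})")
            result.add(chrom, start, end)
    return result


def write_interval_set(intervals: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals.intervals():
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# RNA-editing site lists
# ---------------------------------------------------------------------------

SITE_DIALECTS = {
    # dialect -> (chrom column, position column)
    "REDIPORTAL": ("Region", "Position"),
    "DARNED": ("chrom", "coordinate"),
}


def read_site_list(path: str | Path, dialect: str) -> SiteSet:
    """Read an RNA-editing site list (GRCh38 coordinates, 1-based positions)."""
    dialect = dialect.upper()
    if dialect not in SITE_DIALECTS:
        raise ConfigurationError(
            f"unknown site-list dialect {dialect!r}; expected one of {sorted(SITE_DIALECTS)}"
        )
    chrom_col, pos_col = SITE_DIALECTS[dialect]
    df = pd.read_csv(path, sep="\t", dtype=str)
    if chrom_col not in df.columns or pos_col not in df.columns:
        raise FormatError(f"{path}: expected columns {chrom_col!r}, {pos_col!r} for {dialect}")
    sites = frozenset(
        (normalize_chrom(c), int(p)) for c, p in zip(df[chrom_col], df[pos_col])
    )
    return SiteSet(sites=sites, provenance=dialect)


def write_site_list(sites: Iterable[tuple[str, int]], path: str | Path, dialect: str) -> None:
    dialect = dialect.upper()
    chrom_col, pos_col = SITE_DIALECTS[dialect]
    rows = sorted(set((normalize_chrom(c), int(p)) for c, p in sites))
    if dialect == "DARNED":  # DARNED distributes chromosome names without prefix
        rows = [(c[3:], p) for c, p in rows]
    pd.DataFrame(rows, columns=[chrom_col, pos_col]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotated result table
# ---------------------------------------------------------------------------

def write_annotated_table(
    records: Sequence[VariantRecord],
    features: pd.DataFrame,
    probabilities: Sequence[float],
    classes: Sequence[bool],
    path: str | Path,
    labels: Optional[Sequence[str]] = None,
) -> None:
    """Write the generic entry table: locus, alleles, features, predictions.

    The column order is stable and the table re-reads bit-exactly via
    :func:`read_annotated_table`.
    """
    n = len(records)
    if not (len(features) == len(probabilities) == len(classes) == n):
        raise ValueError("records, features and predictions must align 1:1")
    if labels is not None and len(labels) != n:
        raise ValueError("labels must align 1:1 with records")
    meta = pd.DataFrame({
        "case_id": [r.case_id for r in records],
        "chrom": [r.chrom for r in records],
        "pos": [r.pos for r in records],
        "ref": [r.ref for r in records],
        "alt": [r.alt for r in records],
    })
    out = pd.concat([meta, features.reset_index(drop=True)], axis=1)
    out["pred_prob"] = list(probabilities)
    out["pred_class"] = ["positive" if c else "negative" for c in classes]
    if labels is not None:
        out["truth_label"] = list(labels)
    out.to_csv(path, sep="\t", index=False)


def read_annotated_table(path: str | Path) -> pd.DataFrame:
    # round_trip float parsing makes write->read bit-exact
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
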