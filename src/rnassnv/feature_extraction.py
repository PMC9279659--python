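"""Named feature vectors for the classifier.

Features fall into three categories. Variant level: the Mutect2 site
qualities (TLOD, ECNT, STRANDQ, ROQ, SEQQ, GERMQ, CONTQ, POPAF, NALOD,
NLOD). Genotype level: allele fractions, allelic depths, total depths,
median base/mapping qualities, median read position, read-orientation
counts and fragment lengths. Annotation level: twelve one-hot allelic
change indicators (A>G marks A-to-I editing, G>A marks C-to-U editing on
the opposite strand) plus an integer-coded variant classification.

The canonical 40-name schema is a documented reconstruction: it contains
every feature the model is known to rank or drop, embedded in the standard
FilterMutectCalls field inventory, and is overridable by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import BASES, ConfigurationError, VariantRecord

SUBSTITUTIONS = (
    "A>C", "A>G", "A>T", "C>A", "C>G", "C>T",
    "G>A", "G>C", "G>T", "T>A", "T>C", "T>G",
)

VARIANT_LEVEL = (
    "TLOD", "ECNT", "STRANDQ", "ROQ", "SEQQ", "GERMQ", "CONTQ",
    "POPAF", "NALOD", "NLOD",
)

GENOTYPE_LEVEL = (
    "AF_tumor", "AD_ref_tumor", "AD_alt_tumor", "DP_tumor",
    "AF_normal", "AD_ref_normal", "AD_alt_normal", "DP_normal",
    "MBQ_ref", "MBQ_alt", "MMQ_ref", "MMQ_alt", "MPOS",
    "F1R2_alt_tumor", "F2R1_alt_tumor", "MFRL_ref", "MFRL_alt",
)

ANNOTATION_LEVEL = SUBSTITUTIONS + ("VARIANT_CLASS",)

#: canonical 40-feature schema (10 variant + 17 genotype + 13 annotation)
CANONICAL_SCHEMA = VARIANT_LEVEL + GENOTYPE_LEVEL + ANNOTATION_LEVEL

#: integer codes for the Funcotator-style variant classification; unknown -> OTHER
VARIANT_CLASS_CODES = {
    "OTHER": 0,
    "MISSENSE": 1,
    "NONSENSE": 2,
    "SILENT": 3,
    "SPLICE_SITE": 4,
    "NONSTOP": 5,
    "FIVE_PRIME_UTR": 6,
    "THREE_PRIME_UTR": 7,
    "INTRON": 8,
}


@dataclass
class ImputationPolicy:
    """Values substituted for absent caller fields.

    Absence is informative and bounded: missing Phred-like qualities and
    depths impute to 0; missing POPAF imputes to a ceiling meaning "not
    observed in the population" (Mutect2 caps POPAF at 6).
    """

    quality_default: float = 0.0
    depth_default: float = 0.0
    popaf_ceiling: float = 6.0


def encode_allelic_change(ref: str, alt: str) -> str:
    """Return the substitution category name, e.g. ('A','G') -> 'A>G'."""
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"non-ACGT allele in substitution ({ref!r}>{alt!r})")
    if ref == alt:
        raise ValueError(f"ref == alt ({ref!r}); not a substitution")
    return f"{ref}>{alt}"


def _af_tumor(rec: VariantRecord) -> Optional[float]:
    t = rec.tumor_gt
    if t.af is not None:
        return float(t.af)
    if t.ad_ref is not None and t.ad_alt is not None:
        total = t.ad_ref + t.ad_alt
        return (t.ad_alt / total) if total > 0 else 0.0
    return None


def _af_normal(rec: VariantRecord) -> Optional[float]:
    n = rec.normal_gt
    if n.af is not None:
        return float(n.af)
    if n.ad_ref is not None and n.ad_alt is not None:
        total = n.ad_ref + n.ad_alt
        return (n.ad_alt / total) if total > 0 else 0.0
    return None


# feature name -> (accessor, imputation kind)
_RULES = {
    **{name: ((lambda key: lambda r: r.site_quals.get(key))(name),
              "popaf" if name == "POPAF" else "quality")
       for name in VARIANT_LEVEL},
    "MFRL_ref": (lambda r: r.site_quals.get("MFRL_ref"), "quality"),
    "MFRL_alt": (lambda r: r.site_quals.get("MFRL_alt"), "quality"),
    "AF_tumor": (_af_tumor, "depth"),
    "AD_ref_tumor": (lambda r: r.tumor_gt.ad_ref, "depth"),
    "AD_alt_tumor": (lambda r: r.tumor_gt.ad_alt, "depth"),
    "DP_tumor": (lambda r: r.tumor_gt.depth, "depth"),
    "AF_normal": (_af_normal, "depth"),
    "AD_ref_normal": (lambda r: r.normal_gt.ad_ref, "depth"),
    "AD_alt_normal": (lambda r: r.normal_gt.ad_alt, "depth"),
    "DP_normal": (lambda r: r.normal_gt.depth, "depth"),
    "MBQ_ref": (lambda r: r.tumor_gt.mbq_ref, "quality"),
    "MBQ_alt": (lambda r: r.tumor_gt.mbq_alt, "quality"),
    "MMQ_ref": (lambda r: r.tumor_gt.mmq_ref, "quality"),
    "MMQ_alt": (lambda r: r.tumor_gt.mmq_alt, "quality"),
    "MPOS": (lambda r: r.tumor_gt.mpos, "quality"),
    "F1R2_alt_tumor": (lambda r: r.tumor_gt.f1r2_alt, "depth"),
    "F2R1_alt_tumor": (lambda r: r.tumor_gt.f2r1_alt, "depth"),
}


def extract_features(
    record: VariantRecord,
    schema: Sequence[str] = CANONICAL_SCHEMA,
    policy: ImputationPolicy = ImputationPolicy(),
) -> tuple[dict[str, float], dict[str, bool]]:
    """Map one record to (feature values, imputed-flag mask) per the schema."""
    sub = encode_allelic_change(record.ref, record.alt)
    values: dict[str, float] = {}
    imputed: dict[str, bool] = {}
    for name in schema:
        if name in SUBSTITUTIONS:
            values[name] = 1.0 if name == sub else 0.0
            imputed[name] = False
        elif name == "VARIANT_CLASS":
            vc = record.annotations.get("variant_classification", "OTHER")
            values[name] = float(VARIANT_CLASS_CODES.get(vc.upper(), 0))
            imputed[name] = "variant_classification" not in record.annotations
        elif name in _RULES:
            accessor, kind = _RULES[name]
            raw = accessor(record)
            if raw is None:
                values[name] = (policy.popaf_ceiling if kind == "popaf"
                                else policy.depth_default if kind == "depth"
                                else policy.quality_default)
                imputed[name] = True
            else:
                values[name] = float(raw)
                imputed[name] = False
        else:
            raise ConfigurationError(f"no extraction rule for feature {name!r}")
    return values, imputed


@dataclass
class FeatureMatrix:
    """Row-per-record feature table with a retained missing-value mask."""

    values: pd.DataFrame
    imputed: pd.DataFrame
    schema: tuple[str, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.values)


def build_feature_matrix(
    records: Sequence[VariantRecord],
    schema: Sequence[str] = CANONICAL_SCHEMA,
    policy: ImputationPolicy = ImputationPolicy(),
) -> FeatureMatrix:
    """Build an n_records x n_features matrix; no NaN after imputation."""
    if not schema:
        raise ConfigurationError("feature schema must be nonempty")
    rows, masks = [], []
    for rec in records:
        values, imputed = extract_features(rec, schema, policy)
        rows.append(values)
        masks.append(imputed)
    values_df = pd.DataFrame(rows, columns=list(schema), dtype=float)
    mask_df = pd.DataFrame(masks, columns=list(schema), dtype=bool)
    assert not np.isnan(values_df.to_numpy()).any() if len(values_df) else True
    return FeatureMatrix(values=values_df, imputed=mask_df, schema=tuple(schema))
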