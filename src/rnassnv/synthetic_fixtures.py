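"""Synthetic paired RNA/DNA fixtures with the statistical structure the
framework assumes.

The generator emulates, at desk scale, a tumor cohort in which RNA somatic
SNV candidates are a ~1:8 mixture of true somatic mutations and RNA
artifacts. Artifacts split into rule-matching classes (planted editing
sites, multiallelic loci, immunoglobulin/HLA genes, off-target positions —
together the ~70% the multi-filter removes) and feature-distribution
negatives that only the model can reject. True mutations carry DNA
evidence in a gold-standard table (with a small ambiguous slice present
only in a self-called rescue table, and a small RNA-rescued slice in
neither), an expression model (only a fraction of DNA mutations are
expressed; RNA allele fractions sit above DNA ones, strongly so for
planted allele-specific-expression events), and force-called RNA reference
depths for the unexpressed remainder.

Feature distributions are parametric location-scale families per class —
the classifier consumes features, not reads, so this is the minimal
structure exercising every downstream stage. Everything is deterministic
for a fixed seed; per-record filter fates and truth labels are precomputed
and stored so filters and labelers can be checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .feature_extraction import CANONICAL_SCHEMA, SUBSTITUTIONS
from .io_formats import (
    DnaMutation,
    SampleMetrics,
    VariantRecord,
    write_dna_mutation_table,
    write_site_list,
    write_vcf_records,
)

# --- genome model ----------------------------------------------------------

CHROMS = tuple(f"chr{i}" for i in range(1, 23))
TILE = 10_000
N_TILES = 200
CHROM_LEN = TILE * N_TILES
# per-tile offsets: exon [2000,4000), WES target [2500,4500)
EXON_START, EXON_END = 2000, 4000
TARGET_START, TARGET_END = 2500, 4500
RECORD_LO, RECORD_HI = 2500, 3200      # ordinary on-target records
EDIT_LO, EDIT_HI = 3200, 4000          # planted/decoy editing sites
OFF_LO, OFF_HI = 2000, 2500            # in exon, outside WES target

# special gene-region tiles (immunoglobulin on chr14, HLA on chr6)
SPECIAL_TILES = range(100, 150)
HLA_GENES = ("HLA-A", "HLA-B", "HLA-C", "HLA-DRB1")
IG_GENES = ("IGHV3-23", "IGKV1-5", "IGLV2-14", "IGHG1")

VARIANT_CLASSES = ("MISSENSE", "SILENT", "NONSENSE", "SPLICE_SITE",
                   "FIVE_PRIME_UTR", "THREE_PRIME_UTR", "INTRON")
VARIANT_CLASS_P = (0.55, 0.20, 0.05, 0.05, 0.05, 0.05, 0.05)

TRUE_SOMATIC = "TRUE_SOMATIC"
ART_EDITING = "ART_EDITING"
ART_MULTIALLELIC = "ART_MULTIALLELIC"
ART_IG_HLA = "ART_IG_HLA"
ART_OFFTARGET = "ART_OFFTARGET"
ART_MODEL = "ART_MODEL"

FATE_BY_CATEGORY = {
    TRUE_SOMATIC: "KEPT",
    ART_MODEL: "KEPT",
    ART_OFFTARGET: "target_restriction",
    ART_MULTIALLELIC: "multiallelic",
    ART_EDITING: "editing_sites",
    ART_IG_HLA: "ig_hla",
}


class SimConfigError(ValueError):
    pass


def _spectrum(d: dict[str, float]) -> dict[str, float]:
    assert abs(sum(d.values()) - 1.0) < 1e-9
    return d


#: somatic-like substitution spectrum (smoking-exposure flavored)
TP_SPECTRUM = _spectrum({
    "C>A": 0.26, "C>T": 0.18, "G>T": 0.08, "G>A": 0.08, "A>G": 0.06,
    "T>C": 0.06, "C>G": 0.06, "G>C": 0.05, "A>T": 0.04, "A>C": 0.04,
    "T>A": 0.04, "T>G": 0.05,
})
#: artifact spectrum dominated by A-to-I (A>G) and C-to-U (G>A) editing
TN_SPECTRUM = _spectrum({
    "A>G": 0.30, "G>A": 0.22, "C>T": 0.10, "T>C": 0.10, "C>A": 0.06,
    "G>T": 0.06, "C>G": 0.04, "G>C": 0.03, "A>C": 0.03, "A>T": 0.02,
    "T>A": 0.02, "T>G": 0.02,
})

# per-feature ("normal", loc, scale, lo, hi) or ("poisson1", lam) families;
# the two classes overlap on every axis so discrimination needs the ensemble
CLASS_DISTRIBUTIONS: dict[str, dict[str, tuple]] = {
    "TP": {
        "TLOD": ("normal", 28, 12, 2.5, 200),
        "ECNT": ("poisson1", 0.3),
        "STRANDQ": ("normal", 38, 16, 1, 100),
        "ROQ": ("normal", 70, 18, 1, 93),
        "SEQQ": ("normal", 60, 22, 1, 93),
        "GERMQ": ("normal", 55, 22, 1, 93),
        "CONTQ": ("normal", 60, 25, 1, 93),
        "POPAF": ("normal", 5.4, 0.7, 0, 6),
        "NALOD": ("normal", 2.2, 1.0, -1, 10),
        "NLOD": ("normal", 32, 10, 5, 80),
        "MBQ_ref": ("normal", 32, 3, 10, 40),
        "MBQ_alt": ("normal", 30, 4, 10, 40),
        "MMQ_ref": ("normal", 60, 3, 20, 70),
        "MMQ_alt": ("normal", 55, 6, 20, 70),
        "MPOS": ("normal", 26, 8, 1, 60),
        "MFRL_ref": ("normal", 250, 30, 100, 400),
        "MFRL_alt": ("normal", 250, 30, 100, 400),
    },
    "TN": {
        "TLOD": ("normal", 12, 8, 2.0, 200),
        "ECNT": ("poisson1", 1.2),
        "STRANDQ": ("normal", 18, 12, 1, 100),
        "ROQ": ("normal", 45, 22, 1, 93),
        "SEQQ": ("normal", 50, 24, 1, 93),
        "GERMQ": ("normal", 45, 24, 1, 93),
        "CONTQ": ("normal", 55, 25, 1, 93),
        "POPAF": ("normal", 4.3, 1.3, 0, 6),
        "NALOD": ("normal", 1.4, 1.2, -3, 10),
        "NLOD": ("normal", 28, 11, 5, 80),
        "MBQ_ref": ("normal", 32, 3, 10, 40),
        "MBQ_alt": ("normal", 24, 6, 2, 40),
        "MMQ_ref": ("normal", 60, 3, 20, 70),
        "MMQ_alt": ("normal", 47, 9, 20, 70),
        "MPOS": ("normal", 16, 9, 1, 60),
        "MFRL_ref": ("normal", 250, 30, 100, 400),
        "MFRL_alt": ("normal", 250, 30, 100, 400),
    },
}


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults encode the desk-scale analogue of the training cohort: ~1:8
    post-filter TP:TN imbalance, ~70% of artifacts removable by filter
    rules, ~30% of DNA mutations expressed in RNA, a quarter of expressed
    mutations carrying a planted allele-specific-expression shift, and
    ~15% of unexpressed mutations with a transcribed-but-silent locus.
    """

    n_cases: int = 30
    n_true_per_case: int = 64
    n_artifacts_per_case: Optional[int] = None  # None -> derived from imbalance
    imbalance: float = 8.0                      # target TN:TP label ratio
    editing_site_fraction: float = 0.55         # of artifacts, per removal rule
    multiallelic_fraction: float = 0.05
    ig_hla_fraction: float = 0.05
    offtarget_fraction: float = 0.05
    ambiguous_fraction: float = 0.05            # of true: rescue table only
    rna_rescued_fraction: float = 0.03          # of true: no DNA table at all
    expression_prob: float = 0.30               # DNA mutation expressed in RNA
    ase_fraction: float = 0.25                  # of expressed: planted ASE
    ase_shift: tuple[float, float] = (0.35, 0.50)
    ase_up_prob: float = 0.9
    selective_high_ref_fraction: float = 0.15   # of unexpressed: RNA ref depth > 10
    dna_vaf_beta: tuple[float, float] = (2.5, 5.0)
    tn_af_beta: tuple[float, float] = (1.8, 6.0)
    rna_depth_mean: float = 50.0
    dna_depth_mean: float = 80.0
    n_editing_pool: int = 2000                  # planted-site candidates
    n_editing_decoys: int = 500                 # listed sites hitting no record
    class_distributions: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in CLASS_DISTRIBUTIONS.items()})
    seed: int = 0

    def validate(self) -> None:
        fracs = (self.editing_site_fraction, self.multiallelic_fraction,
                 self.ig_hla_fraction, self.offtarget_fraction)
        if any(f < 0 or f > 1 for f in fracs):
            raise SimConfigError("artifact fractions must lie in [0, 1]")
        if sum(fracs) > 1:
            raise SimConfigError("artifact fractions sum beyond 1")
        if self.ambiguous_fraction + self.rna_rescued_fraction > 1:
            raise SimConfigError("true-record evidence fractions sum beyond 1")
        if not 0 < self.expression_prob <= 1:
            raise SimConfigError("expression_prob must lie in (0, 1]")
        if self.n_cases < 1 or self.n_true_per_case < 0:
            raise SimConfigError("n_cases/n_true_per_case out of range")

    @property
    def removable_fraction(self) -> float:
        return (self.editing_site_fraction + self.multiallelic_fraction
                + self.ig_hla_fraction + self.offtarget_fraction)

    def resolved_artifacts_per_case(self) -> int:
        if self.n_artifacts_per_case is not None:
            return self.n_artifacts_per_case
        kept = 1.0 - self.removable_fraction
        if kept <= 0:
            raise SimConfigError("cannot derive artifact count: no artifacts survive the filter")
        tp_labels = self.n_true_per_case * (1 - self.ambiguous_fraction
                                            - self.rna_rescued_fraction)
        tn_from_true = self.n_true_per_case * self.rna_rescued_fraction
        return max(1, round((self.imbalance * tp_labels - tn_from_true) / kept))


@dataclass
class TruthBundle:
    """Simulated cohort: file paths plus the precomputed ground truth."""

    out_dir: Path
    vcf_paths: dict[str, Path]
    gold_path: Path
    rescue_path: Path
    rediportal_path: Path
    darned_path: Path
    exons_path: Path
    targets_path: Path
    truth_path: Path
    expression_path: Path
    truth: pd.DataFrame
    expression: pd.DataFrame
    contig_lengths: dict[str, int]
    config: SimConfig


# --- drawing helpers -------------------------------------------------------

def _draw(dist: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = dist[0]
    if kind == "normal":
        _, loc, scale, lo, hi = dist
        return np.clip(rng.normal(loc, scale, n), lo, hi)
    if kind == "poisson1":
        return 1.0 + rng.poisson(dist[1], n)
    raise SimConfigError(f"unknown distribution family {kind!r}")


def _nbinom(mean: float, n: int, rng: np.random.Generator, size: float = 6.0,
            lo: int = 4) -> np.ndarray:
    p = size / (size + mean)
    return np.maximum(rng.negative_binomial(size, p, n), lo)


def _draw_subs(spectrum: dict[str, float], n: int, rng) -> np.ndarray:
    names = list(SUBSTITUTIONS)
    probs = np.array([spectrum.get(s, 0.0) for s in names])
    probs = probs / probs.sum()
    return rng.choice(names, size=n, p=probs)


def sample_class_features(
    cls: str,
    n: int,
    config: SimConfig = SimConfig(),
    seed: int = 0,
) -> pd.DataFrame:
    """Draw an n x 40 feature matrix for one class ('TP' or 'TN').

    The TP class has higher TLOD, allele fraction and alt depth by
    construction; artifacts skew toward high reference depth and low
    alternative support.
    """
    if cls not in ("TP", "TN"):
        raise SimConfigError(f"class must be 'TP' or 'TN', got {cls!r}")
    if n < 0:
        raise SimConfigError("n must be non-negative")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    dists = config.class_distributions[cls]
    for name, dist in dists.items():
        cols[name] = _draw(dist, n, rng)
    if cls == "TP":
        af = np.clip(rng.beta(*config.dna_vaf_beta, n)
                     + rng.normal(0, 0.03, n), 0.02, 0.98)
    else:
        af = np.clip(rng.beta(*config.tn_af_beta, n), 0.01, 0.98)
    dp = _nbinom(config.rna_depth_mean, n, rng)
    ad_alt = np.clip(rng.binomial(dp, af), 1, dp)
    cols["AF_tumor"] = af
    cols["DP_tumor"] = dp.astype(float)
    cols["AD_alt_tumor"] = ad_alt.astype(float)
    cols["AD_ref_tumor"] = (dp - ad_alt).astype(float)
    dp_n = _nbinom(config.dna_depth_mean, n, rng, lo=10)
    ad_alt_n = (np.zeros(n, dtype=int) if cls == "TP"
                else np.minimum(rng.poisson(0.4, n), dp_n))
    cols["DP_normal"] = dp_n.astype(float)
    cols["AD_alt_normal"] = ad_alt_n.astype(float)
    cols["AD_ref_normal"] = (dp_n - ad_alt_n).astype(float)
    cols["AF_normal"] = ad_alt_n / dp_n
    cols["F1R2_alt_tumor"] = rng.binomial(ad_alt, 0.5).astype(float)
    cols["F2R1_alt_tumor"] = (ad_alt - cols["F1R2_alt_tumor"]).astype(float)
    subs = _draw_subs(TP_SPECTRUM if cls == "TP" else TN_SPECTRUM, n, rng)
    for s in SUBSTITUTIONS:
        cols[s] = (subs == s).astype(float)
    vclass = rng.choice(VARIANT_CLASSES, size=n, p=VARIANT_CLASS_P)
    from .feature_extraction import VARIANT_CLASS_CODES
    cols["VARIANT_CLASS"] = np.array([VARIANT_CLASS_CODES[v] for v in vclass], float)
    return pd.DataFrame({k: cols[k] for k in CANONICAL_SCHEMA})


# --- position machinery ----------------------------------------------------

def _ordinary_tiles() -> list[tuple[str, int]]:
    tiles = []
    for chrom in CHROMS:
        for t in range(N_TILES):
            if chrom in ("chr6", "chr14") and t in SPECIAL_TILES:
                continue
            tiles.append((chrom, t))
    return tiles


_ORDINARY = _ordinary_tiles()
_SPECIAL = [("chr6", t) for t in SPECIAL_TILES] + [("chr14", t) for t in SPECIAL_TILES]


def _decode(pool: list[tuple[str, int]], lo: int, width: int, idx: np.ndarray):
    """Map flat indices to (chrom, 1-based pos, tile) over a (tile x offset)
    pool; ``lo`` is a 0-based (BED-style) zone boundary."""
    tile_idx, off = np.divmod(idx, width)
    out = []
    for ti, o in zip(tile_idx, off):
        chrom, t = pool[ti]
        out.append((chrom, t * TILE + lo + int(o) + 1, t))
    return out


def _sample_positions(pool, lo, hi, n, rng):
    width = hi - lo
    total = len(pool) * width
    if n > total:
        raise SimConfigError("position pool exhausted; reduce per-case sizes")
    idx = rng.choice(total, size=n, replace=False)
    return _decode(pool, lo, width, idx)


def _gene_for(chrom: str, tile: int) -> str:
    if chrom == "chr6" and tile in SPECIAL_TILES:
        return HLA_GENES[tile % len(HLA_GENES)]
    if chrom == "chr14" and tile in SPECIAL_TILES:
        return IG_GENES[tile % len(IG_GENES)]
    return f"G{chrom[3:]}T{tile}"


# --- the generator ---------------------------------------------------------

def simulate_dataset(config: SimConfig, out_dir: str | Path) -> TruthBundle:
    """Generate the full fixture bundle under ``out_dir``.

    Emits one tumor/normal VCF per case, gold and rescue MAF-like tables,
    REDIportal- and DARNED-style editing-site lists whose union covers all
    planted sites, exon and WES-target BEDs, the per-record truth table
    (label and expected filter fate) and the per-DNA-mutation expression
    table. Deterministic (byte-identical files) for a fixed seed.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # global editing-site pool + decoys; written to the two dialect files
    site_positions = _sample_positions(
        _ORDINARY, EDIT_LO, EDIT_HI,
        config.n_editing_pool + config.n_editing_decoys, rng)
    planted_pool = site_positions[:config.n_editing_pool]
    all_sites = [(c, p) for c, p, _ in site_positions]
    redi = [s for i, s in enumerate(all_sites) if i % 10 < 7]
    darned = [s for i, s in enumerate(all_sites) if i % 10 >= 6]

    n_art = config.resolved_artifacts_per_case()
    n_edit = round(n_art * config.editing_site_fraction)
    n_multi = round(n_art * config.multiallelic_fraction)
    n_ighla = round(n_art * config.ig_hla_fraction)
    n_off = round(n_art * config.offtarget_fraction)
    n_model = n_art - n_edit - n_multi - n_ighla - n_off
    n_true = config.n_true_per_case
    n_dna_only = round(n_true * (1 - config.expression_prob)
                       / config.expression_prob)

    truth_rows: list[dict] = []
    expr_rows: list[dict] = []
    gold: list[DnaMutation] = []
    rescue: list[DnaMutation] = []
    vcf_paths: dict[str, Path] = {}
    contig_lengths = {c: CHROM_LEN for c in CHROMS}

    for case_idx in range(config.n_cases):
        case = f"CASE{case_idx:04d}"
        records: list[VariantRecord] = []

        # one without-replacement draw covers every record-zone consumer
        n_zone = n_true + n_dna_only + n_multi + n_model
        zone = _sample_positions(_ORDINARY, RECORD_LO, RECORD_HI, n_zone, rng)
        true_pos = zone[:n_true]
        dna_only_pos = zone[n_true:n_true + n_dna_only]
        multi_pos = zone[n_true + n_dna_only:n_true + n_dna_only + n_multi]
        model_pos = zone[n_true + n_dna_only + n_multi:]
        ighla_pos = _sample_positions(_SPECIAL, RECORD_LO, RECORD_HI, n_ighla, rng)
        off_pos = _sample_positions(_ORDINARY, OFF_LO, OFF_HI, n_off, rng)
        edit_idx = rng.choice(len(planted_pool), size=n_edit, replace=False)
        edit_pos = [planted_pool[i] for i in edit_idx]

        # true somatic candidates -------------------------------------------
        tp_feats = sample_class_features(
            "TP", n_true, config, seed=int(rng.integers(2**31)))
        evid = rng.random(n_true)
        dna_vaf = np.clip(rng.beta(*config.dna_vaf_beta, n_true), 0.03, 0.95)
        dna_dp = _nbinom(config.dna_depth_mean, n_true, rng, lo=15)
        dna_alt = np.clip(rng.binomial(dna_dp, dna_vaf), 2, dna_dp - 2)
        is_ase = rng.random(n_true) < config.ase_fraction
        shift = rng.uniform(*config.ase_shift, n_true)
        ase_up = rng.random(n_true) < config.ase_up_prob
        rna_af = np.clip(dna_vaf + rng.normal(0, 0.03, n_true), 0.02, 0.98)
        rna_af = np.where(
            is_ase,
            np.clip(dna_vaf + np.where(ase_up, shift, -shift), 0.03, 0.97),
            rna_af)
        # recompute depth-consistent RNA allelic depths for true records
        dp = tp_feats["DP_tumor"].to_numpy().astype(int)
        ad_alt = np.clip(rng.binomial(dp, rna_af), 1, dp - 1)
        tp_feats["AF_tumor"] = rna_af
        tp_feats["AD_alt_tumor"] = ad_alt.astype(float)
        tp_feats["AD_ref_tumor"] = (dp - ad_alt).astype(float)

        for i, (chrom, pos, tile) in enumerate(true_pos):
            sub = _one_hot_sub(tp_feats.iloc[i])
            ref, alt = sub[0], sub[2]
            if evid[i] < config.ambiguous_fraction:
                status, label = "RESCUE", "AMBIGUOUS"
            elif evid[i] < config.ambiguous_fraction + config.rna_rescued_fraction:
                status, label = "NONE", "TN"
            else:
                status, label = "GOLD", "TP"
            mut = DnaMutation(case, chrom, pos, ref, alt,
                              ad_ref=int(dna_dp[i] - dna_alt[i]),
                              ad_alt=int(dna_alt[i]),
                              source="SELF_CALLED" if status == "RESCUE" else "GOLD")
            if status == "GOLD":
                gold.append(mut)
            elif status == "RESCUE":
                rescue.append(mut)
            records.append(_make_record(case, chrom, pos, ref, [alt],
                                        tp_feats.iloc[i], _gene_for(chrom, tile)))
            truth_rows.append(_truth_row(case, chrom, pos, ref, alt,
                                         TRUE_SOMATIC, status, label))
            expr_rows.append({
                "case_id": case, "chrom": chrom, "pos": pos, "ref": ref,
                "alt": alt, "dna_ref": int(dna_dp[i] - dna_alt[i]),
                "dna_alt": int(dna_alt[i]),
                "rna_ref": int(dp[i] - ad_alt[i]), "rna_alt": int(ad_alt[i]),
                "expressed": True, "planted_ase": bool(is_ase[i]),
                "in_gold": status == "GOLD",
            })

        # unexpressed DNA mutations (DNA-only part) -------------------------
        do_vaf = np.clip(rng.beta(*config.dna_vaf_beta, n_dna_only), 0.03, 0.95)
        do_dp = _nbinom(config.dna_depth_mean, n_dna_only, rng, lo=15)
        do_alt = np.clip(rng.binomial(do_dp, do_vaf), 2, do_dp - 2)
        high = rng.random(n_dna_only) < config.selective_high_ref_fraction
        ref_depth = np.where(high,
                             12 + rng.poisson(25, n_dna_only),
                             rng.poisson(3.0, n_dna_only))
        do_subs = _draw_subs(TP_SPECTRUM, n_dna_only, rng)
        for i, (chrom, pos, tile) in enumerate(dna_only_pos):
            ref, alt = do_subs[i][0], do_subs[i][2]
            gold.append(DnaMutation(case, chrom, pos, ref, alt,
                                    ad_ref=int(do_dp[i] - do_alt[i]),
                                    ad_alt=int(do_alt[i]), source="GOLD"))
            expr_rows.append({
                "case_id": case, "chrom": chrom, "pos": pos, "ref": ref,
                "alt": alt, "dna_ref": int(do_dp[i] - do_alt[i]),
                "dna_alt": int(do_alt[i]),
                "rna_ref": int(ref_depth[i]), "rna_alt": 0,
                "expressed": False, "planted_ase": False, "in_gold": True,
            })

        # artifacts ---------------------------------------------------------
        n_all_art = n_edit + n_multi + n_ighla + n_off + n_model
        tn_feats = sample_class_features(
            "TN", n_all_art, config, seed=int(rng.integers(2**31)))
        blocks = (
            (edit_pos, ART_EDITING), (multi_pos, ART_MULTIALLELIC),
            (ighla_pos, ART_IG_HLA), (off_pos, ART_OFFTARGET),
            (model_pos, ART_MODEL),
        )
        row = 0
        for positions, category in blocks:
            for chrom, pos, tile in positions:
                feats = tn_feats.iloc[row]
                sub = _one_hot_sub(feats)
                if category == ART_EDITING:
                    sub = "A>G" if rng.random() < 0.6 else "G>A"
                    feats = feats.copy()
                    for s in SUBSTITUTIONS:
                        feats[s] = 1.0 if s == sub else 0.0
                ref, alt = sub[0], sub[2]
                alts = [alt]
                if category == ART_MULTIALLELIC:
                    alts = [alt, _other_base(ref, alt)]
                records.append(_make_record(case, chrom, pos, ref, alts,
                                            feats, _gene_for(chrom, tile)))
                truth_rows.append(_truth_row(case, chrom, pos, ref, alt,
                                             category, "NONE", "TN"))
                row += 1

        vcf_path = out_dir / f"{case}.vcf"
        write_vcf_records(records, vcf_path, contig_lengths)
        vcf_paths[case] = vcf_path

    # resource files --------------------------------------------------------
    gold_path = out_dir / "gold.maf.tsv"
    rescue_path = out_dir / "rescue.maf.tsv"
    write_dna_mutation_table(gold, gold_path)
    write_dna_mutation_table(rescue, rescue_path)
    redi_path = out_dir / "editing_rediportal.tsv"
    darned_path = out_dir / "editing_darned.tsv"
    write_site_list(redi, redi_path, "REDIPORTAL")
    write_site_list(darned, darned_path, "DARNED")
    exons_path = out_dir / "exons.bed"
    targets_path = out_dir / "targets.bed"
    _write_tiled_bed(exons_path, EXON_START, EXON_END)
    _write_tiled_bed(targets_path, TARGET_START, TARGET_END)

    truth = pd.DataFrame(truth_rows)
    expression = pd.DataFrame(expr_rows)
    truth_path = out_dir / "truth.tsv"
    expression_path = out_dir / "expression_truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    expression.to_csv(expression_path, sep="\t", index=False)

    return TruthBundle(
        out_dir=out_dir, vcf_paths=vcf_paths, gold_path=gold_path,
        rescue_path=rescue_path, rediportal_path=redi_path,
        darned_path=darned_path, exons_path=exons_path,
        targets_path=targets_path, truth_path=truth_path,
        expression_path=expression_path, truth=truth, expression=expression,
        contig_lengths=contig_lengths, config=config,
    )


def emit_expression_truth(bundle: TruthBundle) -> pd.DataFrame:
    """Per-DNA-mutation expression truth (already computed by the generator)."""
    return bundle.expression


# --- record assembly -------------------------------------------------------

def _one_hot_sub(feats: pd.Series) -> str:
    for s in SUBSTITUTIONS:
        if feats[s] == 1.0:
            return s
    raise AssertionError("no substitution indicator set")


def _other_base(ref: str, alt: str) -> str:
    for b in "ACGT":
        if b not in (ref, alt):
            return b
    raise AssertionError


_CODE_TO_CLASS = None


def _class_name(code: float) -> str:
    global _CODE_TO_CLASS
    if _CODE_TO_CLASS is None:
        from .feature_extraction import VARIANT_CLASS_CODES
        _CODE_TO_CLASS = {v: k for k, v in VARIANT_CLASS_CODES.items()}
    return _CODE_TO_CLASS[int(code)]


def _make_record(case, chrom, pos, ref, alts, feats, gene) -> VariantRecord:
    site_quals = {k: float(feats[k]) for k in
                  ("TLOD", "ECNT", "STRANDQ", "ROQ", "SEQQ", "GERMQ", "CONTQ",
                   "POPAF", "NALOD", "NLOD", "MFRL_ref", "MFRL_alt")}
    tumor = SampleMetrics(
        ad_ref=int(feats["AD_ref_tumor"]), ad_alt=int(feats["AD_alt_tumor"]),
        af=float(feats["AF_tumor"]), depth=int(feats["DP_tumor"]),
        mbq_ref=float(feats["MBQ_ref"]), mbq_alt=float(feats["MBQ_alt"]),
        mmq_ref=float(feats["MMQ_ref"]), mmq_alt=float(feats["MMQ_alt"]),
        mpos=float(feats["MPOS"]),
        f1r2_alt=int(feats["F1R2_alt_tumor"]), f2r1_alt=int(feats["F2R1_alt_tumor"]),
    )
    normal = SampleMetrics(
        ad_ref=int(feats["AD_ref_normal"]), ad_alt=int(feats["AD_alt_normal"]),
        af=round(float(feats["AF_normal"]), 4), depth=int(feats["DP_normal"]),
    )
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alts=list(alts),
        site_quals=site_quals, tumor_gt=tumor, normal_gt=normal,
        annotations={"gene": gene,
                     "variant_classification": _class_name(feats["VARIANT_CLASS"])},
        case_id=case,
    )


def _truth_row(case, chrom, pos, ref, alt, category, dna_status, label) -> dict:
    return {
        "case_id": case, "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
        "category": category, "dna_status": dna_status,
        "expected_label": label, "expected_fate": FATE_BY_CATEGORY[category],
    }


def _write_tiled_bed(path: Path, lo: int, hi: int) -> None:
    with open(path, "w") as fh:
        for chrom in CHROMS:
            for t in range(N_TILES):
                fh.write(f"{chrom}\t{t * TILE + lo}\t{t * TILE + hi}\n")


def small_config(**overrides) -> SimConfig:
    """A fast, fully-featured configuration for unit-scale fixtures."""
    base = SimConfig(n_cases=3, n_true_per_case=24, seed=7)
    return replace(base, **overrides)
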