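"""End-to-end orchestration: simulate → filter → label → train → predict →
integrate.

This is the glue the acceptance workflow and the CLI ``run`` command use.
Problem sizes for selection and tuning are capped by stratified
subsampling (settings below) so a full cohort run stays desk-scale; the
procedure itself (RFECV, grid search, weighted forest) is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import classifier as clf
from . import integration as integ
from .feature_extraction import build_feature_matrix
from .io_formats import (
    read_dna_mutation_table,
    read_interval_set,
    read_site_list,
    read_vcf_records,
)
from .multifilter import MultiFilterConfig, apply_multifilter
from .synthetic_fixtures import SimConfig, TruthBundle, simulate_dataset
from .truthset import AMBIGUOUS, assign_labels, split_train_test


@dataclass
class PipelineSettings:
    """Model-fitting knobs for a cohort run."""

    split_ratio: float = 0.9
    selection_folds: int = 10
    selection_estimators: int = 30
    selection_max_rows: Optional[int] = 5000
    grid: dict = field(default_factory=lambda: {
        "max_depth": [10, None], "min_samples_leaf": [1, 2]})
    grid_folds: int = 10
    grid_estimators: int = 100
    grid_max_rows: Optional[int] = 5000
    final_estimators: int = 300
    threshold: float = 0.5


def load_filter_resources(bundle: TruthBundle) -> MultiFilterConfig:
    sites = read_site_list(bundle.rediportal_path, "REDIPORTAL").union(
        read_site_list(bundle.darned_path, "DARNED"))
    return MultiFilterConfig(
        editing_sites=sites,
        exons=read_interval_set(bundle.exons_path),
        wes_targets=read_interval_set(bundle.targets_path),
    )


def run_end_to_end(
    sim_config: SimConfig,
    workdir: str | Path,
    settings: PipelineSettings = PipelineSettings(),
) -> dict:
    """Run the whole framework on a simulated cohort; return a results dict.

    Every reported number is measured from the run: filter accounting
    against generator truth, held-out test metrics at the 0.5 threshold,
    PR-AUC, gold-standard precision/recall from the tri-partition,
    per-case medians, expression ratios and ASE recovery.
    """
    workdir = Path(workdir)
    bundle = simulate_dataset(sim_config, workdir / "fixtures")
    seed = sim_config.seed

    fconfig = load_filter_resources(bundle)
    gold = read_dna_mutation_table(bundle.gold_path, source="GOLD")
    rescue = read_dna_mutation_table(bundle.rescue_path, source="SELF_CALLED")

    kept_records = []
    for case, vcf_path in sorted(bundle.vcf_paths.items()):
        records = read_vcf_records(vcf_path, case_id=case)
        kept, _ = apply_multifilter(records, fconfig)
        kept_records.extend(kept)

    # filter accounting against generator truth
    truth = bundle.truth
    truth_keys = set(zip(truth.case_id, truth.chrom, truth.pos, truth.ref, truth.alt))
    kept_keys = {r.key() for r in kept_records}
    is_artifact = truth.category != "TRUE_SOMATIC"
    art_keys = set(zip(*[truth[c][is_artifact] for c in
                         ("case_id", "chrom", "pos", "ref", "alt")]))
    true_keys = truth_keys - art_keys
    artifact_removal_fraction = 1 - len(art_keys & kept_keys) / len(art_keys)
    true_loss_fraction = 1 - len(true_keys & kept_keys) / len(true_keys)

    # labeling and split
    labeled = assign_labels(kept_records, gold, rescue)
    matrix = build_feature_matrix(kept_records)
    y = np.array([lr.label for lr in labeled])
    model_mask = y != AMBIGUOUS
    X_model = matrix.values.loc[model_mask].reset_index(drop=True)
    y_model = y[model_mask]
    split = split_train_test(X_model, y_model, ratio=settings.split_ratio, seed=seed)

    # feature selection, tuning, training
    selected = clf.select_features(
        split.train_X, split.train_y, folds=settings.selection_folds,
        seed=seed, n_estimators=settings.selection_estimators,
        max_rows=settings.selection_max_rows)
    params = clf.tune_hyperparameters(
        split.train_X[selected], split.train_y, grid=settings.grid,
        folds=settings.grid_folds, seed=seed,
        n_estimators=settings.grid_estimators, max_rows=settings.grid_max_rows)
    bundle_model = clf.train_classifier(
        split.train_X, split.train_y, selected, params=params,
        n_estimators=settings.final_estimators, seed=seed)

    # held-out evaluation
    probs, classes = clf.predict(bundle_model, split.test_X, settings.threshold)
    cm = clf.compute_confusion(split.test_y, classes)
    metrics = clf.compute_metrics(cm)
    pr = clf.pr_curve_auc(probs, split.test_y)

    # integrate every kept candidate against the gold DNA set
    all_probs, all_classes = clf.predict(bundle_model, matrix.values,
                                         settings.threshold)
    gold_by_case: dict[str, set] = {}
    for m in gold:
        gold_by_case.setdefault(m.case_id, set()).add(m.key())
    preds_by_case: dict[str, list] = {}
    for rec, positive in zip(kept_records, all_classes):
        preds_by_case.setdefault(rec.case_id, []).append((rec.key(), bool(positive)))
    parts = {case: integ.partition_rna_dna(preds, gold_by_case.get(case, set()))
             for case, preds in sorted(preds_by_case.items())}

    pooled = integ.TriPartition()
    for p in parts.values():
        pooled.overlap_pos |= p.overlap_pos
        pooled.overlap_neg |= p.overlap_neg
        pooled.rna_only_pos |= p.rna_only_pos
        pooled.rna_only_neg |= p.rna_only_neg
        pooled.dna_only |= p.dna_only
    gold_precision, gold_recall = integ.gold_standard_pr(pooled)
    case_metrics = integ.per_case_metrics(parts)

    # expression ratios per case from force-called reference depths
    expr = bundle.expression
    ref_depth = {
        (r.case_id, r.chrom, r.pos, r.ref, r.alt): r.rna_ref
        for r in expr[~expr.expressed].itertuples()
    }
    ratios = [integ.expression_ratios(parts[c], ref_depth) for c in parts]
    expr_vals = [r.expression_ratio for r in ratios if r.expression_ratio is not None]
    sel_vals = [r.selective_expression_ratio for r in ratios
                if r.selective_expression_ratio is not None]

    # allele-specific expression recovery on the expressed, gold-backed part
    tested = flagged = over = 0
    planted_tested = 0
    for r in expr[expr.expressed & expr.in_gold].itertuples():
        if not integ.passes_het_gate((r.dna_ref, r.dna_alt), (r.rna_ref, r.rna_alt)):
            continue
        tested += 1
        planted_tested += int(r.planted_ase)
        result = integ.ase_test((r.rna_ref, r.rna_alt), (r.dna_ref, r.dna_alt))
        if result.is_ase:
            flagged += 1
            over += int(result.direction == integ.MUTANT_OVER)

    return {
        "bundle": bundle,
        "model": bundle_model,
        "selected_features": selected,
        "params": params,
        "confusion": cm,
        "metrics": metrics,
        "pr_auc": pr.auc,
        "test_precision": metrics.precision,
        "test_recall": metrics.recall,
        "artifact_removal_fraction": artifact_removal_fraction,
        "true_loss_fraction": true_loss_fraction,
        "n_candidates": len(truth),
        "n_kept": len(kept_records),
        "gold_precision": gold_precision,
        "gold_recall": gold_recall,
        "median_case_precision": case_metrics.median_precision,
        "median_case_recall": case_metrics.median_recall,
        "median_expression_ratio": float(np.median(expr_vals)) if expr_vals else None,
        "median_selective_expression_ratio": float(np.median(sel_vals)) if sel_vals else None,
        "ase_n_tested": tested,
        "ase_flagged_fraction": flagged / tested if tested else None,
        "ase_planted_fraction": planted_tested / tested if tested else None,
        "ase_mutant_over_fraction": over / flagged if flagged else None,
        "per_case_table": case_metrics.table,
        "importances": clf.feature_importance(bundle_model),
        "parts": parts,
    }
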