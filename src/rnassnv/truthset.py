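"""DNA-evidence truth labels and train/test splitting.

A multi-filtered RNA candidate is labeled by where its (case, chrom, pos,
ref, alt) key falls: in the gold-standard DNA set (consensus GDC calls) it
is a true positive; only in the self-called rescue set it is ambiguous —
real DNA evidence, but below the consensus bar; in neither it is a true
negative (no DNA support). Ambiguous records are excluded from training
and testing but kept for the audit table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .io_formats import DnaMutation, VariantRecord

TP, AMBIGUOUS, TN = "TP", "AMBIGUOUS", "TN"


@dataclass
class LabeledRecord:
    record: VariantRecord
    label: str

    @property
    def key(self) -> tuple:
        return self.record.key()


def _key_set(muts: Iterable[DnaMutation]) -> set[tuple]:
    return {m.key() for m in muts}


def assign_labels(
    rna_records: Sequence[VariantRecord],
    gold: Iterable[DnaMutation],
    rescue: Iterable[DnaMutation] = (),
) -> list[LabeledRecord]:
    """Partition RNA candidates into TP / AMBIGUOUS / TN by DNA evidence."""
    gold_keys = _key_set(gold)
    rescue_keys = _key_set(rescue)
    out = []
    for rec in rna_records:
        key = rec.key()
        if key in gold_keys:
            label = TP
        elif key in rescue_keys:
            label = AMBIGUOUS
        else:
            label = TN
        out.append(LabeledRecord(rec, label))
    return out


@dataclass
class DatasetSplit:
    train_X: pd.DataFrame
    train_y: np.ndarray
    test_X: pd.DataFrame
    test_y: np.ndarray
    ratio: float
    seed: int


def split_train_test(
    X: pd.DataFrame,
    y: Sequence[str],
    ratio: float = 0.9,
    seed: int = 0,
) -> DatasetSplit:
    """Stratified 9:1 (by default) split of TP/TN labeled features.

    AMBIGUOUS records must be removed by the caller before splitting.
    """
    y = np.asarray(y)
    if AMBIGUOUS in y:
        raise ValueError("AMBIGUOUS records must be excluded before splitting")
    counts = pd.Series(y).value_counts()
    if set(counts.index) != {TP, TN}:
        raise ValueError(f"expected both TP and TN labels, got {sorted(set(y))}")
    if counts.min() < 10:
        raise ValueError(f"fewer than 10 records in a class: {counts.to_dict()}")
    train_X, test_X, train_y, test_y = train_test_split(
        X, y, train_size=ratio, stratify=y, random_state=seed,
    )
    return DatasetSplit(
        train_X=train_X.reset_index(drop=True), train_y=train_y,
        test_X=test_X.reset_index(drop=True), test_y=test_y,
        ratio=ratio, seed=seed,
    )
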