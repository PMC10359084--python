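"""Evaluation metrics: ROC-AUC, macro F1 and the adjusted Rand index.

Thin, validated wrappers around scikit-learn.  ROC-AUC equals the
probability that a random positive outscores a random negative (ties counted
half); F1 is macro-averaged over the classes present in the truth, so a
class never predicted contributes 0; ARI is the permutation-model-corrected
Rand index, 1 for identical partitions and ~0 for independent ones.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score, f1_score, roc_auc_score

from .errors import UndefinedMetricError, ValidationError


def _check_lengths(a: Sequence, b: Sequence) -> None:
    if len(a) != len(b):
        raise ValidationError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValidationError("empty inputs")


def roc_auc(scores: Sequence[float], truth: Sequence[int]) -> float:
    """Area under the ROC curve for binary truth labels."""
    _check_lengths(scores, truth)
    truth_arr = np.asarray(truth)
    classes = np.unique(truth_arr)
    if len(classes) != 2:
        raise UndefinedMetricError(
            f"ROC-AUC needs both classes present, got {classes.tolist()}"
        )
    return float(roc_auc_score(truth_arr, np.asarray(scores, dtype=float)))


def f1_multiclass(
    pred: Sequence, truth: Sequence, average: str = "macro"
) -> float:
    """F1 score averaged over the classes present in the truth."""
    _check_lengths(pred, truth)
    truth_arr = np.asarray(truth)
    return float(
        f1_score(
            truth_arr,
            np.asarray(pred),
            labels=np.unique(truth_arr),
            average=average,
            zero_division=0,
        )
    )


def adjusted_rand_index(labels1: Sequence, labels2: Sequence) -> float:
    """Chance-corrected agreement of two partitions of the same items."""
    _check_lengths(labels1, labels2)
    if len(labels1) < 2:
        raise ValidationError("ARI needs at least 2 items")
    return float(adjusted_rand_score(np.asarray(labels1), np.asarray(labels2)))
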