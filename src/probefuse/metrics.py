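"""Classification metrics for episodic evaluation.

The primary metric is macro one-vs-rest multi-class AUROC with midrank tie
handling (delegated to scikit-learn's trapezoidal ROC integration); classes
absent from the query are dropped from the macro average with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.metrics import roc_auc_score


def multiclass_auroc(y_true, scores, return_per_class: bool = False):
    """Macro-averaged one-vs-rest AUROC.

    `scores` is [n, C] of class scores (any monotone transform of
    probabilities works; ROC is rank-based). Ties receive the midrank
    convention, so constant scores give 0.5.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    n_classes = scores.shape[1]
    per_class: dict[int, float] = {}
    for c in range(n_classes):
        mask = y_true == c
        if mask.all() or not mask.any():
            warnings.warn(
                f"class {c} has no positives or no negatives in the query; "
                "dropped from the macro AUROC", stacklevel=2,
            )
            continue
        per_class[c] = float(roc_auc_score(mask.astype(int), scores[:, c]))
    if not per_class:
        raise ValueError("AUROC undefined: no class has both outcomes")
    macro = float(np.mean(list(per_class.values())))
    if return_per_class:
        return macro, per_class
    return macro


def accuracy(y_true, scores) -> float:
    """Arg-max match rate."""
    y_true = np.asarray(y_true)
    pred = np.asarray(scores).argmax(axis=1)
    return float((pred == y_true).mean())
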