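"""AUC helpers shared by the selection and modeling stages."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score

from .synthcohort import POSITIVE


def binarize_labels(labels) -> np.ndarray:
    """Map cohort labels to {0, 1} with RTLI+ as the positive class."""
    labels = np.asarray(labels)
    if labels.dtype.kind in "OUS":
        return (labels == POSITIVE).astype(int)
    return labels.astype(int)


def auc(scores, labels) -> float:
    """Area under the ROC curve: the Mann-Whitney concordance probability
    with tied scores counted 1/2.  Requires both classes present."""
    y = binarize_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=np.float64)))


def auc_columns(score_matrix: np.ndarray, labels) -> np.ndarray:
    """Column-wise AUC of an (n, p) score matrix via midranks (ties 1/2)."""
    y = binarize_labels(labels)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(score_matrix, axis=0)
    rank_sum_pos = ranks[y == 1].sum(axis=0)
    return (rank_sum_pos - n1 * (n1 + 1) / 2.0) / (n1 * n0)
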