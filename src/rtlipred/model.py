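"""Time-indexed dataset assembly, random-forest training and evaluation.

Three models predict injury k scans before its confirmation at scan N:
model k (k = 1, 2, 3) uses each positive subject's scan at time N-k.  To
soften class imbalance, every negative subject contributes its scans at
N-1, N-2 and N-3 to all three models (pooling).  Splitting is at subject
level, stratified by label, so no subject crosses the train/test boundary.

Evaluation is the AUC of the forest's positive-class probability on the
held-out rows, with a mean and 95% percentile CI from B class-stratified
bootstrap resamples of the test rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .containers import parse_feature_name
from .metrics import auc, binarize_labels

SEQUENCE_SETS = (("CET1w",), ("T2w",), ("CET1w", "T2w"))
TOPK_DEFAULT = (1, 5, 10, 15, 20)


@dataclass
class ModelDataset:
    """Rows (subject, time) x selected feature columns for one model index."""

    k: int
    X: pd.DataFrame
    y: np.ndarray
    subjects: np.ndarray

    @property
    def n_rows(self) -> int:
        return len(self.X)

    def restrict(self, subject_ids) -> "ModelDataset":
        keep = np.isin(self.subjects, np.asarray(list(subject_ids)))
        return ModelDataset(
            k=self.k, X=self.X.iloc[keep], y=self.y[keep], subjects=self.subjects[keep]
        )


@dataclass
class EvalResult:
    """Bootstrap evaluation of one model configuration."""

    mean_auc: float
    ci_lo: float
    ci_hi: float
    B: int
    model_k: int = 0
    tissue: str = ""
    sequences: tuple = ()
    top_k: int = 0
    n_train: int = 0
    n_test: int = 0

    def __post_init__(self) -> None:
        if not (self.ci_lo <= self.mean_auc <= self.ci_hi):
            raise ValueError("CI must bracket the mean AUC")


def select_columns(
    features: pd.DataFrame,
    tissue: str | None = None,
    sequences: Sequence[str] | None = None,
    families: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Restrict a feature table by tissue, sequence set and/or feature family."""
    keep = []
    for c in features.columns:
        meta = parse_feature_name(c)
        if tissue is not None and meta["tissue"] != tissue:
            continue
        if sequences is not None and meta["sequence"] not in sequences:
            continue
        if families is not None and meta["family"] not in families:
            continue
        keep.append(c)
    return features[keep]


def assemble_model_dataset(
    features: pd.DataFrame,
    labels: pd.Series,
    k: int,
    selected: Sequence[str] | None = None,
    n_scans: int | None = None,
) -> ModelDataset:
    """Build the model-k dataset from a (subject, time)-indexed feature table.

    Positives contribute their scan at time N-k only; negatives contribute
    scans N-1, N-2 and N-3.  N is ``n_scans`` if given, else each subject's
    largest time index in the table.  Subjects missing a required scan are
    dropped with a warning.  Rows are sorted canonically by (subject, time).
    """
    if k not in (1, 2, 3):
        raise ValueError("model index k must be 1, 2 or 3")
    ylab = binarize_labels(labels)
    label_of = dict(zip(labels.index, ylab))

    rows: list[tuple[str, int]] = []
    y: list[int] = []
    for sid in sorted(labels.index):
        if sid not in features.index.get_level_values(0):
            warnings.warn(f"subject {sid} absent from feature table; dropped", stacklevel=2)
            continue
        times = sorted(features.loc[sid].index)
        N = n_scans if n_scans is not None else max(times)
        wanted = [N - k] if label_of[sid] == 1 else [N - 3, N - 2, N - 1]
        missing = [t for t in wanted if t not in times]
        if missing:
            warnings.warn(
                f"subject {sid} missing scan(s) {missing} for model {k}; dropped", stacklevel=2
            )
            continue
        for t in wanted:
            rows.append((sid, t))
            y.append(label_of[sid])

    X = features.loc[rows]
    if selected is not None:
        X = X[list(selected)]
    return ModelDataset(
        k=k,
        X=X,
        y=np.asarray(y, dtype=int),
        subjects=np.asarray([sid for sid, _ in rows]),
    )


def split_train_test(subjects, labels, fraction: float = 0.8, seed: int = 0):
    """Stratified subject-level split; returns (train_ids, test_ids)."""
    subjects = np.asarray(subjects)
    yb = binarize_labels(labels)
    train, test = train_test_split(
        subjects, train_size=fraction, stratify=yb, random_state=seed, shuffle=True
    )
    return sorted(train), sorted(test)


def train_rf(
    train: ModelDataset,
    n_estimators: int = 500,
    max_features: str = "sqrt",
    seed: int = 0,
) -> RandomForestClassifier:
    """Fit the random forest on canonically ordered rows (deterministic under seed)."""
    if len(np.unique(train.y)) < 2:
        raise ValueError("training set has a single class")
    order = np.lexsort((train.X.index.get_level_values(1), train.subjects))
    clf = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features=max_features,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(train.X.to_numpy()[order], train.y[order])
    return clf


def predict_scores(clf: RandomForestClassifier, dataset: ModelDataset) -> np.ndarray:
    """Positive-class probability scores."""
    return clf.predict_proba(dataset.X.to_numpy())[:, 1]


def bootstrap_auc_ci(scores, labels, B: int = 1000, seed: int = 0, **meta) -> EvalResult:
    """Mean AUC and percentile 95% CI over B class-stratified row resamples."""
    scores = np.asarray(scores, dtype=np.float64)
    yb = binarize_labels(labels)
    idx_by_class = [np.flatnonzero(yb == c) for c in (0, 1)]
    if any(len(ix) == 0 for ix in idx_by_class):
        raise ValueError("both classes must be present in the test set")
    rng = np.random.default_rng(seed)
    aucs = np.empty(B)
    for b in range(B):
        rows = np.concatenate([rng.choice(ix, size=len(ix), replace=True) for ix in idx_by_class])
        aucs[b] = auc(scores[rows], yb[rows])
    lo, hi = np.quantile(aucs, [0.025, 0.975])
    mean = float(aucs.mean())
    return EvalResult(
        mean_auc=mean,
        ci_lo=float(min(lo, mean)),
        ci_hi=float(max(hi, mean)),
        B=B,
        **meta,
    )


def evaluate_model(
    train: ModelDataset,
    test: ModelDataset,
    n_estimators: int = 500,
    seed: int = 0,
    B: int = 1000,
    **meta,
) -> tuple[EvalResult, np.ndarray]:
    """Train on ``train``, score ``test``, bootstrap the test AUC."""
    clf = train_rf(train, n_estimators=n_estimators, seed=seed)
    scores = predict_scores(clf, test)
    result = bootstrap_auc_ci(
        scores, test.y, B=B, seed=seed, n_train=train.n_rows, n_test=test.n_rows, **meta
    )
    return result, scores
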