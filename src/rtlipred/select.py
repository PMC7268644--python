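"""Two-stage feature selection.

Stage 1 — **ReliefF screening**: features are weighted by how well they
separate each instance from its nearest neighbours of the other class
relative to its own class (k nearest hits / misses, feature values scaled to
[0, 1] for the diff).  Within each texture-parameter combination the two
top-weighted texture features are retained; with the default 240-point grid
that is 480 features.

Stage 2 — **0.632+ bootstrap AUC ranking**: subjects are resampled B times
with class stratification ("imbalance-adjusted": each class is resampled to
its own size so prevalence is preserved in every in-bag set).  Each candidate
feature is scored univariately (the feature value itself is the decision
score, oriented so its apparent AUC is >= 0.5) and aggregated with the 0.632+
estimator

    AUC_0.632+ = (1/B) sum_b [(1 - a(b)) AUC(X,X) + a(b) AUC'(X*b, X*b(0))]

with AUC' = max{0.5, oob AUC},  a(b) = 0.632 / (1 - 0.368 R(b)) and the
relative overfitting rate R(b) = 1 if oob <= 0.5; (apparent - oob)/(apparent
- 0.5) if 2 > apparent/AUC' > 1; else 0 (clipped to [0, 1]).  When the
apparent AUC is <= 0.5 the middle branch would divide by a non-positive
number, so only the first/third branches apply.

Because the parameter-set screen can by construction only return texture
features, the ranking stage considers the screened texture features together
with all non-texture features present in the table; a texture-only top list
is therefore a finding, not a tautology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import is_texture_feature, parse_feature_name
from .metrics import auc, auc_columns, binarize_labels


# ---------------------------------------------------------------------------
# ReliefF
# ---------------------------------------------------------------------------


def relief_weights(
    X,
    y,
    n_neighbors: int = 10,
    n_sampled: int | None = None,
    rng: np.random.Generator | None = None,
):
    """ReliefF feature weights for a two-class table.

    Weights are accumulated per sampled instance as (mean scaled |diff| to the
    k nearest misses) minus (to the k nearest hits) and averaged over sampled
    instances; ties in neighbour distance are broken by instance index.  A
    class smaller than ``n_neighbors + 1`` reduces k with a warning.  Returns
    a Series when ``X`` is a DataFrame, else an ndarray.
    """
    columns = X.columns if isinstance(X, pd.DataFrame) else None
    Xa = np.asarray(X, dtype=np.float64)
    if not np.isfinite(Xa).all():
        raise ValueError("non-finite feature values; clean the table first")
    yb = binarize_labels(y)
    n, p = Xa.shape
    for cls in (0, 1):
        if (yb == cls).sum() < 2:
            raise ValueError("need at least 2 instances per class")

    # per-feature [0,1] scaling for the diff function
    lo = Xa.min(axis=0)
    rng_span = Xa.max(axis=0) - lo
    span = np.where(rng_span > 0, rng_span, 1.0)
    Xs = (Xa - lo) / span
    Xs[:, rng_span == 0] = 0.0  # constant features contribute zero diff

    if n_sampled is None or n_sampled >= n:
        sampled = np.arange(n)
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        sampled = np.sort(rng.choice(n, size=n_sampled, replace=False))

    d2 = ((Xs[:, None, :] - Xs[None, :, :]) ** 2).sum(axis=-1)
    np.fill_diagonal(d2, np.inf)

    W = np.zeros(p)
    warned = False
    for i in sampled:
        for is_hit in (True, False):
            pool = np.flatnonzero((yb == yb[i]) if is_hit else (yb != yb[i]))
            pool = pool[pool != i]
            k = min(n_neighbors, len(pool))
            if k < n_neighbors and not warned:
                warnings.warn(
                    f"class too small for k={n_neighbors} neighbours; using k={k}",
                    stacklevel=2,
                )
                warned = True
            order = pool[np.argsort(d2[i, pool], kind="stable")[:k]]
            mean_diff = np.abs(Xs[order] - Xs[i]).mean(axis=0)
            W += mean_diff if not is_hit else -mean_diff
    W /= len(sampled)
    if columns is not None:
        return pd.Series(W, index=columns)
    return W


def select_top_per_paramset(weights: pd.Series, n_per_set: int = 2) -> list[str]:
    """Keep the ``n_per_set`` top-weighted texture features of every parameter set.

    Ties in weight break lexicographically by feature name.  Non-texture
    features (which carry no texture parameters) are not candidates here.
    """
    groups: dict[str, list[tuple[float, str]]] = {}
    for name, w in weights.items():
        meta = parse_feature_name(name)
        if meta["family"] == "nontexture":
            continue
        groups.setdefault(meta["params"], []).append((float(w), name))
    selected: list[str] = []
    for params in sorted(groups):
        cands = [(w, name) for w, name in groups[params] if np.isfinite(w)]
        if len(cands) < n_per_set:
            raise ValueError(
                f"parameter set {params!r} has {len(cands)} finite-weight features; "
                f"need {n_per_set}"
            )
        cands.sort(key=lambda t: (-t[0], t[1]))
        selected.extend(name for _, name in cands[:n_per_set])
    return selected


class ReliefFSelector(BaseEstimator):
    """ReliefF screen keeping the top ``n_per_set`` texture features per parameter set.

    Attributes after ``fit``: ``weights_`` (Series), ``ranking_`` (feature
    names, descending weight) and ``selected_`` (the 2-per-parameter-set
    screen, 480 features on the default grid).
    """

    def __init__(self, n_neighbors: int = 10, n_sampled: int | None = None, n_per_set: int = 2, random_state: int = 0):
        self.n_neighbors = n_neighbors
        self.n_sampled = n_sampled
        self.n_per_set = n_per_set
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y):
        self.weights_ = relief_weights(
            X,
            y,
            n_neighbors=self.n_neighbors,
            n_sampled=self.n_sampled,
            rng=np.random.default_rng(self.random_state),
        )
        order = sorted(self.weights_.items(), key=lambda t: (-t[1], t[0]))
        self.ranking_ = [name for name, _ in order]
        self.selected_ = select_top_per_paramset(self.weights_, self.n_per_set)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.selected_]


# ---------------------------------------------------------------------------
# stratified subject-level bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapSplit:
    """One bootstrap replicate: in-bag subject indices (a multiset) and
    out-of-bag indices (subjects absent from the bag)."""

    replicate: int
    in_bag: np.ndarray
    out_of_bag: np.ndarray


def bootstrap_resample(subjects, labels, B: int, seed: int = 0, max_retries: int = 1000) -> list[BootstrapSplit]:
    """B class-stratified subject-level bootstrap draws.

    Each class is resampled with replacement to its own size, so every in-bag
    set preserves the cohort's class proportions.  A replicate whose
    out-of-bag set misses a class is redrawn (bounded retries).
    Returns splits holding indices into ``subjects``.
    """
    subjects = np.asarray(subjects)
    yb = binarize_labels(labels)
    if len(subjects) != len(yb):
        raise ValueError("subjects and labels length mismatch")
    idx_by_class = [np.flatnonzero(yb == c) for c in (0, 1)]
    if any(len(ix) == 0 for ix in idx_by_class):
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    splits = []
    for b in range(B):
        for _ in range(max_retries):
            bag = np.concatenate(
                [rng.choice(ix, size=len(ix), replace=True) for ix in idx_by_class]
            )
            oob = np.setdiff1d(np.arange(len(subjects)), bag)
            if len(oob) and len(np.unique(yb[oob])) == 2:
                break
        else:
            raise RuntimeError(f"replicate {b}: could not draw an out-of-bag set with both classes")
        splits.append(BootstrapSplit(replicate=b, in_bag=np.sort(bag), out_of_bag=oob))
    return splits


# ---------------------------------------------------------------------------
# 0.632+ bootstrap AUC
# ---------------------------------------------------------------------------


@dataclass
class Bootstrap0632Result:
    """Per-replicate diagnostics and the aggregated 0.632+ AUC."""

    apparent: float
    oob: np.ndarray
    auc_prime: np.ndarray
    overfit_rate: np.ndarray
    weight: np.ndarray
    auc_0632plus: float


def auc_0632plus(apparent: float, oob) -> Bootstrap0632Result:
    """Aggregate apparent and out-of-bag AUCs with the 0.632+ estimator."""
    oob = np.asarray(oob, dtype=np.float64)
    if not (0.0 <= apparent <= 1.0) or np.any(oob < 0) or np.any(oob > 1):
        raise ValueError("AUCs must lie in [0, 1]")
    if oob.size == 0:
        raise ValueError("need at least one out-of-bag AUC")
    auc_prime = np.maximum(0.5, oob)
    R = np.zeros_like(oob)
    low = oob <= 0.5
    R[low] = 1.0
    if apparent > 0.5:
        ratio = np.full_like(oob, np.nan)
        np.divide(apparent, auc_prime, out=ratio, where=auc_prime > 0)
        mid = ~low & (ratio > 1.0) & (ratio < 2.0)
        R[mid] = (apparent - oob[mid]) / (apparent - 0.5)
    np.clip(R, 0.0, 1.0, out=R)
    a = 0.632 / (1.0 - 0.368 * R)
    agg = float(np.mean((1.0 - a) * apparent + a * auc_prime))
    return Bootstrap0632Result(
        apparent=float(apparent),
        oob=oob,
        auc_prime=auc_prime,
        overfit_rate=R,
        weight=a,
        auc_0632plus=agg,
    )


class Bootstrap632Ranker(BaseEstimator):
    """Rank candidate features by univariate 0.632+ bootstrap AUC.

    Each feature's own value is its decision score, with the orientation
    that makes the apparent AUC >= 0.5.  Resampling is subject-level and
    class-stratified.  After ``fit``: ``scores_`` (Series of 0.632+ AUCs),
    ``ranking_`` (descending, ties by name), ``selected_`` (top ``top_n``)
    and ``results_`` (per-feature :class:`Bootstrap0632Result`).
    """

    def __init__(self, B: int = 1000, top_n: int = 20, random_state: int = 0):
        self.B = B
        self.top_n = top_n
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y, subject_ids=None):
        """Fit on a feature table.

        ``y`` gives one label per row; ``subject_ids`` (default: the first
        index level) ties rows to subjects for subject-level resampling.
        """
        if subject_ids is None:
            if not isinstance(X.index, pd.MultiIndex):
                raise ValueError("pass subject_ids or use a (subject, time) MultiIndex")
            subject_ids = X.index.get_level_values(0).to_numpy()
        subject_ids = np.asarray(subject_ids)
        Xa = np.asarray(X, dtype=np.float64)
        if not np.isfinite(Xa).all():
            raise ValueError("non-finite feature values; clean the table first")
        yb = binarize_labels(y)

        subjects, first_pos = np.unique(subject_ids, return_index=True)
        subj_labels = yb[first_pos]
        for s in subjects:
            if len(np.unique(yb[subject_ids == s])) != 1:
                raise ValueError(f"subject {s!r} has inconsistent labels")

        splits = bootstrap_resample(subjects, subj_labels, B=self.B, seed=self.random_state)
        rows_of = {s: np.flatnonzero(subject_ids == s) for s in subjects}

        raw_apparent = auc_columns(Xa, yb)
        orient = np.where(raw_apparent >= 0.5, 1.0, -1.0)
        apparent = np.maximum(raw_apparent, 1.0 - raw_apparent)

        oob_aucs = np.empty((len(splits), Xa.shape[1]))
        for b, split in enumerate(splits):
            rows = np.concatenate([rows_of[subjects[i]] for i in split.out_of_bag])
            raw = auc_columns(Xa[rows], yb[rows])
            oob_aucs[b] = np.where(orient > 0, raw, 1.0 - raw)

        self.results_ = {}
        scores = {}
        for j, name in enumerate(X.columns):
            res = auc_0632plus(float(apparent[j]), oob_aucs[:, j])
            self.results_[name] = res
            scores[name] = res.auc_0632plus
        self.scores_ = pd.Series(scores)
        self.ranking_ = [n for n, _ in sorted(scores.items(), key=lambda t: (-t[1], t[0]))]
        self.selected_ = self.ranking_[: self.top_n]
        self.splits_ = splits
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.selected_]


def rank_features_0632(
    X: pd.DataFrame, y, B: int = 1000, top_n: int = 20, seed: int = 0, subject_ids=None
) -> Bootstrap632Ranker:
    """Functional wrapper around :class:`Bootstrap632Ranker`."""
    return Bootstrap632Ranker(B=B, top_n=top_n, random_state=seed).fit(X, y, subject_ids=subject_ids)


def screen_candidates(X: pd.DataFrame, selected_texture: list[str]) -> list[str]:
    """Candidate set for the ranking stage: screened texture features plus all
    non-texture features present in the table."""
    nontexture = [c for c in X.columns if not is_texture_feature(c)]
    return list(selected_texture) + nontexture
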