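"""Intensity standardization and gray/white tissue segmentation.

Two steps mirror common MRI radiomics practice:

1. **Histogram-landmark intensity standardization** (two-step learn /
   transform).  Landmark intensities at fixed percentiles are learned from a
   set of same-sequence volumes after affine anchoring of the extreme
   landmarks to a fixed output range; each volume is then mapped onto the
   learned standard scale by a piecewise-linear monotone map.  In the
   pipeline the model is fitted separately per sequence and per follow-up
   time point.

2. **HMRF-EM tissue segmentation**: a two-component Gaussian mixture fitted
   by hard EM with a synchronous Iterated-Conditional-Modes smoothing pass
   per iteration (Potts prior with weight ``beta`` over the 6-neighbourhood),
   restricted to an ROI.  Classes are reported in ascending-mean order, so on
   T1-like intensities class 0 is gray matter and class 1 white matter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ScanVolume

DEFAULT_PERCENTILES = (0.01, 0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90, 0.99)


def _volume_data(v) -> np.ndarray:
    return v.data if isinstance(v, ScanVolume) else np.asarray(v, dtype=np.float64)


def _strictly_increasing(x: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """Nudge ties upward so the landmark sequence is strictly increasing."""
    out = x.copy()
    for i in range(1, len(out)):
        if out[i] <= out[i - 1]:
            out[i] = out[i - 1] + eps
    return out


class HistogramNormalizer(BaseEstimator, TransformerMixin):
    """Landmark-based intensity standardization.

    Parameters
    ----------
    percentiles : sequence of float in (0, 1), strictly increasing
        Probabilities at which landmark intensities are taken.  Default:
        deciles plus 1% / 99% tails.
    output_range : (float, float)
        The extreme landmarks of every volume are anchored affinely onto this
        range before averaging; transformed intensities are clipped to it.

    Attributes
    ----------
    standard_scale_ : ndarray
        Learned landmark intensities on the standard scale (strictly
        increasing).
    sequence_ : str or None
        Sequence tag of the training volumes, if they carried one.
    """

    def __init__(self, percentiles=DEFAULT_PERCENTILES, output_range=(0.0, 100.0)):
        self.percentiles = percentiles
        self.output_range = output_range

    def _check_params(self) -> np.ndarray:
        p = np.asarray(self.percentiles, dtype=float)
        if p.ndim != 1 or len(p) < 2:
            raise ValueError("need at least two percentiles")
        if np.any(p <= 0) or np.any(p >= 1) or np.any(np.diff(p) <= 0):
            raise ValueError("percentiles must be strictly increasing within (0, 1)")
        lo, hi = self.output_range
        if not hi > lo:
            raise ValueError("output_range must be increasing")
        return p

    def _landmarks(self, data: np.ndarray, p: np.ndarray) -> np.ndarray:
        lm = np.quantile(data, p)
        if lm[-1] <= lm[0]:
            raise ValueError("degenerate (constant) volume: landmarks collapse")
        return lm

    def fit(self, volumes, y=None):
        """Learn the standard scale from >= 2 same-sequence volumes."""
        p = self._check_params()
        volumes = list(volumes)
        if len(volumes) < 2:
            raise ValueError("need at least two volumes to learn a standard scale")
        seqs = {v.sequence for v in volumes if isinstance(v, ScanVolume)}
        if len(seqs) > 1:
            raise ValueError(f"mixed sequences in training volumes: {sorted(seqs)}")
        self.sequence_ = seqs.pop() if seqs else None

        lo, hi = self.output_range
        mapped = []
        for v in volumes:
            lm = self._landmarks(_volume_data(v), p)
            mapped.append(lo + (lm - lm[0]) * (hi - lo) / (lm[-1] - lm[0]))
        self.standard_scale_ = _strictly_increasing(np.mean(mapped, axis=0))
        self.percentiles_ = p
        return self

    def transform_volume(self, v):
        """Map one volume onto the standard scale (piecewise-linear, monotone)."""
        if not hasattr(self, "standard_scale_"):
            raise ValueError("HistogramNormalizer is not fitted")
        if isinstance(v, ScanVolume) and self.sequence_ is not None and v.sequence != self.sequence_:
            raise ValueError(
                f"model learned for sequence {self.sequence_!r}, got volume of {v.sequence!r}"
            )
        data = _volume_data(v)
        lm = _strictly_increasing(self._landmarks(data, self.percentiles_))
        out = np.interp(data, lm, self.standard_scale_)
        out = np.clip(out, *self.output_range)
        if isinstance(v, ScanVolume):
            return v.with_data(out)
        return out

    def transform(self, volumes):
        return [self.transform_volume(v) for v in volumes]


def learn_histogram_landmarks(volumes, percentiles=DEFAULT_PERCENTILES, output_range=(0.0, 100.0)) -> HistogramNormalizer:
    return HistogramNormalizer(percentiles=percentiles, output_range=output_range).fit(volumes)


def apply_histogram_transform(v, model: HistogramNormalizer):
    return model.transform_volume(v)


# ---------------------------------------------------------------------------
# HMRF-EM segmentation
# ---------------------------------------------------------------------------


@dataclass
class TissueSegmentation:
    """Result of the two-class HMRF-EM segmentation.

    ``labels`` has the volume's shape with values {0, 1} inside the ROI
    (ascending class mean) and -1 outside.
    """

    labels: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    beta: float
    n_iter: int
    converged: bool
    degenerate: bool


def _neighbor_class_counts(labels: np.ndarray, roi: np.ndarray, k: int) -> np.ndarray:
    """Per-voxel count of 6-neighbours inside the ROI currently labelled k."""
    match = (labels == k) & roi
    counts = np.zeros(labels.shape, dtype=np.int32)
    for axis in range(3):
        for shift in (1, -1):
            counts += np.roll(match, shift, axis=axis) & _valid_shift_mask(labels.shape, axis, shift)
    return counts


def _valid_shift_mask(shape, axis, shift) -> np.ndarray:
    """Mask of voxels whose neighbour at -shift along axis exists (no wraparound)."""
    m = np.ones(shape, dtype=bool)
    idx = [slice(None)] * 3
    idx[axis] = slice(0, 1) if shift == 1 else slice(-1, None)
    m[tuple(idx)] = False
    return m


class HmrfSegmenter(BaseEstimator):
    """Two-class Gaussian HMRF segmentation of an ROI.

    EM is initialized by a median split of the ROI intensities (deterministic,
    no random state).  Each iteration re-labels all ROI voxels synchronously by
    minimizing Gaussian negative log-likelihood plus ``beta`` times the number
    of disagreeing 6-neighbours, then re-estimates class means/variances from
    the hard labels.  ``beta = 0`` reduces to classification EM on a 2-GMM.
    """

    N_CLASSES = 2
    _VAR_FLOOR = 1e-6

    def __init__(self, beta: float = 0.5, max_iter: int = 50, tol: float = 1e-3):
        self.beta = beta
        self.max_iter = max_iter
        self.tol = tol

    def fit_predict(self, volume, roi) -> TissueSegmentation:
        data = _volume_data(volume)
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != data.shape:
            raise ValueError("ROI shape does not match volume shape")
        n = int(roi.sum())
        if n < 2 * self.N_CLASSES:
            raise ValueError(f"ROI has {n} voxels; need at least {2 * self.N_CLASSES}")

        x = data[roi]
        degenerate = bool(np.ptp(x) == 0)
        labels = np.full(data.shape, -1, dtype=np.int8)
        labels[roi] = (x > np.median(x)).astype(np.int8)

        means = np.zeros(2)
        variances = np.full(2, self._VAR_FLOOR)
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            for k in range(2):
                sel = labels[roi] == k
                if sel.any():
                    means[k] = x[sel].mean()
                    variances[k] = max(float(x[sel].var()), self._VAR_FLOOR)
            energies = []
            for k in range(2):
                e = 0.5 * np.log(2 * np.pi * variances[k]) + (data - means[k]) ** 2 / (2 * variances[k])
                agree = _neighbor_class_counts(labels, roi, k)
                total = sum(_neighbor_class_counts(labels, roi, j) for j in range(2)) if self.beta else 0
                e = e + self.beta * (total - agree)
                energies.append(e)
            new_in_roi = np.argmin(np.stack([e[roi] for e in energies]), axis=0).astype(np.int8)
            changed = np.mean(new_in_roi != labels[roi])
            labels[roi] = new_in_roi
            if changed < self.tol:
                converged = True
                break

        # final parameter update and ascending-mean relabelling
        for k in range(2):
            sel = labels[roi] == k
            if sel.any():
                means[k] = x[sel].mean()
                variances[k] = max(float(x[sel].var()), self._VAR_FLOOR)
        counts = [int((labels[roi] == k).sum()) for k in range(2)]
        if 0 in counts:
            degenerate = True
        if means[0] > means[1]:
            swapped = labels.copy()
            swapped[roi] = 1 - labels[roi]
            labels = swapped
            means = means[::-1].copy()
            variances = variances[::-1].copy()
        if degenerate:
            warnings.warn("degenerate segmentation: one class is empty", stacklevel=2)
        return TissueSegmentation(
            labels=labels,
            means=means,
            variances=variances,
            beta=self.beta,
            n_iter=n_iter,
            converged=converged or degenerate,
            degenerate=degenerate,
        )


def segment_tissues(volume, roi, beta: float = 0.5, max_iter: int = 50, tol: float = 1e-3) -> TissueSegmentation:
    return HmrfSegmenter(beta=beta, max_iter=max_iter, tol=tol).fit_predict(volume, roi)


def isolated_voxel_count(seg: TissueSegmentation, roi) -> int:
    """Number of ROI voxels whose every in-ROI 6-neighbour carries the other label.

    Used to check the smoothing effect of ``beta`` empirically.
    """
    roi = np.asarray(roi, dtype=bool)
    labels = seg.labels
    isolated = 0
    for k in range(2):
        mine = (labels == k) & roi
        same = _neighbor_class_counts(labels, roi, k)
        other = _neighbor_class_counts(labels, roi, 1 - k)
        isolated += int(np.sum(mine & (same == 0) & (other > 0)))
    return isolated
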