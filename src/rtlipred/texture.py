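"""3D radiomic texture feature engine.

For every combination of four texture parameters —

* ``ratio``: weight applied to the six mixed (band-pass) sub-bands of a
  one-level 3D wavelet decomposition (LLL and HHH keep weight 1; all weights
  are renormalized by their mean, so ``ratio = 1`` is the identity filter),
* ``scale``: isotropic voxel size in mm the volume is resampled to
  (``None`` = the native in-plane spacing),
* ``quantizer``: ``"equalprob"`` (bin edges at ROI intensity quantiles) or
  ``"uniform"`` (equal-width bins over the ROI intensity range),
* ``n_levels``: number of gray levels after quantization —

43 texture features are computed on the quantized ROI: 3 global histogram
moments, 9 gray-level co-occurrence (GLCM), 13 gray-level run-length (GLRLM),
13 gray-level size-zone (GLSZM) and 5 neighbourhood gray-tone difference
(NGTDM) features.  With the default 5 x 6 x 2 x 4 grid this yields
43 * 240 = 10,320 texture values per tissue per sequence, plus 4 non-texture
(shape) features computed once per tissue from the native-resolution mask.

Degenerate inputs (constant ROI, single gray level, single voxel) produce
documented constants rather than NaN: GLCM collapses to a point mass (energy
1, contrast 0, correlation 0 by convention), size/run variation measures are
0, and NGTDM coarseness is capped at 1e6.

Pipeline order per grid point: wavelet filter -> isotropic resample (trilinear
for intensities, nearest-neighbour for masks) -> quantize -> features.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import (
    ROISet,
    ScanVolume,
    SEQUENCES,
    TISSUES,
    feature_name,
    format_params,
)

GLOBAL_FEATURES = ("variance", "skewness", "kurtosis")
GLCM_FEATURES = (
    "energy",
    "contrast",
    "entropy",
    "homogeneity",
    "correlation",
    "sum_average",
    "variance",
    "dissimilarity",
    "autocorrelation",
)
GLRLM_FEATURES = (
    "sre", "lre", "gln", "rln", "rp",
    "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge", "glv", "rlv",
)
GLSZM_FEATURES = (
    "sze", "lze", "gln", "zsn", "zp",
    "lgze", "hgze", "szlge", "szhge", "lzlge", "lzhge", "glv", "zsv",
)
NGTDM_FEATURES = ("coarseness", "contrast", "busyness", "complexity", "strength")
NONTEXTURE_FEATURES = ("volume", "size", "solidity", "eccentricity")

N_TEXTURE_TYPES = (
    len(GLOBAL_FEATURES)
    + len(GLCM_FEATURES)
    + len(GLRLM_FEATURES)
    + len(GLSZM_FEATURES)
    + len(NGTDM_FEATURES)
)
assert N_TEXTURE_TYPES == 43

COARSENESS_CAP = 1e6

#: the 13 unique 3D directions at Chebyshev distance 1 (first nonzero positive)
DIRECTIONS_13 = tuple(
    d
    for d in itertools.product((-1, 0, 1), repeat=3)
    if d != (0, 0, 0) and (d > (0, 0, 0))
)
assert len(DIRECTIONS_13) == 13


@dataclass(frozen=True)
class TextureParams:
    """One texture-parameter combination."""

    ratio: float
    scale: float | None
    quantizer: str
    n_levels: int

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("wavelet ratio must be positive")
        if self.scale is not None and self.scale <= 0:
            raise ValueError("scale must be positive (or None for native in-plane)")
        if self.quantizer not in ("equalprob", "uniform"):
            raise ValueError(f"unknown quantizer {self.quantizer!r}")
        if self.n_levels < 2:
            raise ValueError("need at least 2 gray levels")

    @property
    def tag(self) -> str:
        return format_params(self.ratio, self.scale, self.quantizer, self.n_levels)


@dataclass(frozen=True)
class TextureParameterGrid:
    """Full factorial grid of texture parameters.

    Defaults follow common radiomics framework conventions: 5 wavelet ratios,
    6 isotropic scales (1-5 mm plus native in-plane), both quantizers, 4
    gray-level counts — 240 combinations, 10,320 texture features.
    """

    ratios: tuple = (0.5, 2.0 / 3.0, 1.0, 1.5, 2.0)
    scales: tuple = (1.0, 2.0, 3.0, 4.0, 5.0, None)
    quantizers: tuple = ("equalprob", "uniform")
    gray_levels: tuple = (8, 16, 32, 64)

    def __iter__(self):
        for r in self.ratios:
            for s in self.scales:
                for q in self.quantizers:
                    for n in self.gray_levels:
                        yield TextureParams(r, s, q, n)

    def __len__(self) -> int:
        return len(self.ratios) * len(self.scales) * len(self.quantizers) * len(self.gray_levels)

    @property
    def n_texture_features(self) -> int:
        return N_TEXTURE_TYPES * len(self)


# ---------------------------------------------------------------------------
# filtering, resampling, quantization
# ---------------------------------------------------------------------------


def wavelet_bandpass_filter(v: ScanVolume, ratio: float, basis: str = "sym8") -> ScanVolume:
    """Weight the band-pass sub-bands of a one-level 3D DWT and reconstruct.

    The six mixed sub-bands (aad ... dda) receive weight ``ratio``; the pure
    low (aaa) and pure high (ddd) sub-bands keep weight 1; all weights are
    divided by their mean, so ``ratio = 1`` reproduces the input exactly and
    the filter is linear in the input.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    try:
        wavelet = pywt.Wavelet(basis)
    except ValueError as exc:
        raise ValueError(f"unknown wavelet basis {basis!r}") from exc
    data = v.data
    if min(data.shape) < 2:
        raise ValueError("volume too small for one wavelet decomposition level")
    coeffs = pywt.dwtn(data, wavelet, mode="symmetric")
    weights = {k: (1.0 if k in ("aaa", "ddd") else float(ratio)) for k in coeffs}
    mean_w = np.mean(list(weights.values()))
    scaled = {k: c * (weights[k] / mean_w) for k, c in coeffs.items()}
    rec = pywt.idwtn(scaled, wavelet, mode="symmetric")
    rec = rec[tuple(slice(0, n) for n in data.shape)]
    return v.with_data(rec)


def resample_isotropic(v: ScanVolume, scale: float | None, order: int = 1) -> ScanVolume:
    """Resample onto an isotropic grid of spacing ``scale`` mm.

    Trilinear interpolation by default (``order=1``); pass ``order=0`` for
    masks.  ``scale=None`` uses the native in-plane spacing.  The output grid
    covers the original physical extent (``grid_mode`` zoom semantics).
    """
    s = float(v.spacing[0]) if scale is None else float(scale)
    if s <= 0:
        raise ValueError("scale must be positive")
    in_shape = np.array(v.data.shape)
    spacing = np.array(v.spacing)
    out_shape = np.maximum(1, np.round(in_shape * spacing / s).astype(int))
    if np.array_equal(out_shape, in_shape) and np.allclose(spacing, s):
        return v.with_data(v.data.copy(), spacing=(s, s, s))
    factors = out_shape / in_shape
    out = ndimage.zoom(v.data, factors, order=order, mode="nearest", grid_mode=True, prefilter=False)
    return v.with_data(out, spacing=(s, s, s))


def resample_mask(mask: np.ndarray, spacing, scale: float | None) -> np.ndarray:
    """Nearest-neighbour resampling of a binary mask onto the isotropic grid."""
    vol = ScanVolume(data=mask.astype(np.float64), spacing=spacing)
    out = resample_isotropic(vol, scale, order=0)
    return out.data > 0.5


@dataclass
class QuantizedROI:
    """ROI intensities quantized to integer gray levels 1..n_levels.

    ``levels`` and ``mask`` are cropped to the ROI bounding box; ``levels``
    is 0 outside the mask.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    degenerate: bool = False

    @property
    def values(self) -> np.ndarray:
        return self.levels[self.mask]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def quantize(data: np.ndarray, mask: np.ndarray, quantizer: str, n_levels: int) -> QuantizedROI:
    """Quantize ROI intensities to ``n_levels`` gray levels.

    ``"uniform"``: equal-width bins over [min, max] of the ROI intensities.
    ``"equalprob"``: bin edges at ROI intensity quantiles k/n_levels.
    A constant ROI maps every voxel to level 1 and sets the degenerate flag.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    if quantizer not in ("equalprob", "uniform"):
        raise ValueError(f"unknown quantizer {quantizer!r}")
    if n_levels < 2:
        raise ValueError("need at least 2 gray levels")
    data = np.asarray(data, dtype=np.float64)

    slices = ndimage.find_objects(mask.astype(np.int8))[0]
    mask_c = mask[slices]
    vals = data[slices][mask_c]

    levels = np.zeros(mask_c.shape, dtype=np.int32)
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmax <= vmin:
        levels[mask_c] = 1
        return QuantizedROI(levels=levels, mask=mask_c, n_levels=n_levels, degenerate=True)

    if quantizer == "uniform":
        width = (vmax - vmin) / n_levels
        lv = np.floor((vals - vmin) / width).astype(np.int32) + 1
        np.clip(lv, 1, n_levels, out=lv)
    else:
        edges = np.quantile(vals, np.arange(1, n_levels) / n_levels)
        lv = np.searchsorted(edges, vals, side="right").astype(np.int32) + 1
    levels[mask_c] = lv
    return QuantizedROI(levels=levels, mask=mask_c, n_levels=n_levels, degenerate=False)


# ---------------------------------------------------------------------------
# feature families
# ---------------------------------------------------------------------------


def global_features(q: QuantizedROI) -> dict[str, float]:
    """Sample variance, Fisher skewness and excess kurtosis of the quantized ROI.

    Zero-variance ROIs return 0 for all three by policy.
    """
    x = q.values.astype(np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 ROI voxels")
    var = float(x.var(ddof=1))
    if x.var() == 0:
        return {"variance": 0.0, "skewness": 0.0, "kurtosis": 0.0}
    c = x - x.mean()
    m2 = np.mean(c**2)
    m3 = np.mean(c**3)
    m4 = np.mean(c**4)
    return {
        "variance": var,
        "skewness": float(m3 / m2**1.5),
        "kurtosis": float(m4 / m2**2 - 3.0),
    }


def _shift_pairs(arr: np.ndarray, mask: np.ndarray, d: tuple[int, int, int]):
    """Values at (voxel, voxel+d) for all voxel pairs fully inside the mask."""
    sl_a, sl_b = [], []
    for n, step in zip(arr.shape, d):
        if step == 0:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
        elif step == 1:
            sl_a.append(slice(0, n - 1))
            sl_b.append(slice(1, n))
        else:
            sl_a.append(slice(1, n))
            sl_b.append(slice(0, n - 1))
    sl_a, sl_b = tuple(sl_a), tuple(sl_b)
    valid = mask[sl_a] & mask[sl_b]
    return arr[sl_a][valid], arr[sl_b][valid]


def glcm_matrix(q: QuantizedROI) -> np.ndarray:
    """Symmetric normalized GLCM pooled over the 13 unique directions at distance 1.

    If the ROI yields no valid voxel pair, the matrix collapses to a point
    mass at the modal gray level (smallest on ties).
    """
    ng = q.n_levels
    counts = np.zeros(ng * ng, dtype=np.float64)
    for d in DIRECTIONS_13:
        a, b = _shift_pairs(q.levels, q.mask, d)
        if a.size:
            counts += np.bincount((a - 1) * ng + (b - 1), minlength=ng * ng)
    P = counts.reshape(ng, ng)
    P = P + P.T
    total = P.sum()
    if total == 0:
        modal = int(np.bincount(q.values).argmax())
        P[modal - 1, modal - 1] = 1.0
        total = 1.0
    return P / total


def glcm_features(q: QuantizedROI) -> dict[str, float]:
    P = glcm_matrix(q)
    ng = q.n_levels
    i = np.arange(1, ng + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    pi = P.sum(axis=1)  # marginal (symmetric)
    mu = float((i * pi).sum())
    var = float(((i - mu) ** 2 * pi).sum())
    nz = P > 0
    if var > 0:
        corr = float(((I * J * P).sum() - mu * mu) / var)
    else:
        corr = 0.0  # point-mass matrix: correlation undefined, 0 by policy
    return {
        "energy": float((P**2).sum()),
        "contrast": float(((I - J) ** 2 * P).sum()),
        "entropy": float(-(P[nz] * np.log2(P[nz])).sum()),
        "homogeneity": float((P / (1.0 + np.abs(I - J))).sum()),
        "correlation": corr,
        "sum_average": float(((I + J) * P).sum()),
        "variance": var,
        "dissimilarity": float((np.abs(I - J) * P).sum()),
        "autocorrelation": float((I * J * P).sum()),
    }


def glrlm_matrix(q: QuantizedROI) -> np.ndarray:
    """Run-length matrix R[level, length] pooled over the 13 directions.

    A run is a maximal collinear sequence of equal gray level inside the ROI;
    every ROI voxel belongs to exactly one run per direction, so per
    direction sum(length * count) equals the ROI voxel count.
    """
    coords = np.argwhere(q.mask)
    lv = q.levels[q.mask]
    n = coords.shape[0]
    max_len = int(max(q.mask.shape))
    R = np.zeros((q.n_levels, max_len), dtype=np.float64)
    for d in DIRECTIONS_13:
        dv = np.array(d)
        i0 = int(np.flatnonzero(dv)[0])
        t = coords[:, i0] * int(np.sign(dv[i0]))
        anchor = coords - t[:, None] * dv
        order = np.lexsort((t, anchor[:, 2], anchor[:, 1], anchor[:, 0]))
        ts, ls = t[order], lv[order]
        anc = anchor[order]
        new_run = np.ones(n, dtype=bool)
        if n > 1:
            same_line = (anc[1:] == anc[:-1]).all(axis=1)
            contiguous = ts[1:] == ts[:-1] + 1
            same_level = ls[1:] == ls[:-1]
            new_run[1:] = ~(same_line & contiguous & same_level)
        run_id = np.cumsum(new_run) - 1
        lengths = np.bincount(run_id)
        run_levels = ls[new_run]
        np.add.at(R, (run_levels - 1, lengths - 1), 1.0)
    return R


def _rl_zone_features(M: np.ndarray, n_voxels_weighted: float, names: tuple[str, ...]) -> dict[str, float]:
    """Shared 13-feature formulas for run-length and size-zone matrices.

    ``M[i-1, l-1]`` counts runs (zones) of gray level i and length (size) l;
    ``n_voxels_weighted`` is the voxel total the emphasis-percentage feature
    divides by (13 x ROI voxels for pooled runs, ROI voxels for zones).
    """
    n_runs = M.sum()
    if n_runs == 0:
        return {name: 0.0 for name in names}
    i = np.arange(1, M.shape[0] + 1, dtype=np.float64)
    l = np.arange(1, M.shape[1] + 1, dtype=np.float64)
    p = M / n_runs
    pi = p.sum(axis=1)
    pl = p.sum(axis=0)
    mu_i = (i * pi).sum()
    mu_l = (l * pl).sum()
    vals = {
        names[0]: (pl / l**2).sum(),           # short emphasis
        names[1]: (pl * l**2).sum(),           # long emphasis
        names[2]: (M.sum(axis=1) ** 2).sum() / n_runs,  # gray-level non-uniformity
        names[3]: (M.sum(axis=0) ** 2).sum() / n_runs,  # length non-uniformity
        names[4]: n_runs / n_voxels_weighted,  # percentage
        names[5]: (pi / i**2).sum(),           # low gray-level emphasis
        names[6]: (pi * i**2).sum(),           # high gray-level emphasis
        names[7]: (p / np.outer(i**2, l**2)).sum(),
        names[8]: (p * np.outer(i**2, 1.0 / l**2)).sum(),
        names[9]: (p * np.outer(1.0 / i**2, l**2)).sum(),
        names[10]: (p * np.outer(i**2, l**2)).sum(),
        names[11]: (pi * (i - mu_i) ** 2).sum(),  # gray-level variance
        names[12]: (pl * (l - mu_l) ** 2).sum(),  # length variance
    }
    return {k: float(v) for k, v in vals.items()}


def glrlm_features(q: QuantizedROI) -> dict[str, float]:
    R = glrlm_matrix(q)
    return _rl_zone_features(R, float(len(DIRECTIONS_13) * q.n_voxels), GLRLM_FEATURES)


def glszm_matrix(q: QuantizedROI) -> np.ndarray:
    """Size-zone matrix S[level, size]: 26-connected zones of equal gray level."""
    structure = np.ones((3, 3, 3), dtype=bool)
    sizes_by_level: list[tuple[int, int]] = []
    max_size = 1
    for level in np.unique(q.values):
        lab, n_lab = ndimage.label((q.levels == level) & q.mask, structure=structure)
        if n_lab:
            sizes = np.bincount(lab.ravel())[1:]
            for s in sizes:
                sizes_by_level.append((int(level), int(s)))
                max_size = max(max_size, int(s))
    S = np.zeros((q.n_levels, max_size), dtype=np.float64)
    for level, size in sizes_by_level:
        S[level - 1, size - 1] += 1.0
    return S


def glszm_features(q: QuantizedROI) -> dict[str, float]:
    S = glszm_matrix(q)
    return _rl_zone_features(S, float(q.n_voxels), GLSZM_FEATURES)


def _neighborhood_sums(q: QuantizedROI):
    """26-neighbourhood sum and count of in-ROI gray levels, per voxel."""
    lv = q.levels.astype(np.float64)
    m = q.mask.astype(np.float64)
    nb_sum = np.zeros_like(lv)
    nb_cnt = np.zeros_like(lv)
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        pad = [(max(s, 0), max(-s, 0)) for s in d]
        sl = tuple(slice(p[1], n + p[1]) for p, n in zip(pad, lv.shape))
        nb_sum += np.pad(lv * m, pad)[sl]
        nb_cnt += np.pad(m, pad)[sl]
    return nb_sum, nb_cnt


def ngtdm_table(q: QuantizedROI):
    """Amadasun NGTDM: per-level probabilities p_i and summed deviations s_i.

    Voxels with at least one in-ROI 26-neighbour contribute
    ``|level - mean(neighbour levels)|`` to s at their own level.
    """
    nb_sum, nb_cnt = _neighborhood_sums(q)
    valid = q.mask & (nb_cnt > 0)
    lv = q.levels[valid].astype(np.float64)
    mean_nb = nb_sum[valid] / nb_cnt[valid]
    dev = np.abs(lv - mean_nb)
    n_i = np.bincount(q.levels[valid], minlength=q.n_levels + 1)[1:].astype(np.float64)
    s_i = np.zeros(q.n_levels)
    np.add.at(s_i, q.levels[valid] - 1, dev)
    total = n_i.sum()
    p_i = n_i / total if total > 0 else n_i
    return p_i, s_i, total


def ngtdm_features(q: QuantizedROI) -> dict[str, float]:
    p, s, n = ngtdm_table(q)
    i = np.arange(1, q.n_levels + 1, dtype=np.float64)
    nz = p > 0
    ngp = int(nz.sum())
    ps = float((p * s).sum())

    coarseness = 1.0 / ps if ps > 0 else COARSENESS_CAP
    coarseness = min(coarseness, COARSENESS_CAP)

    if ngp <= 1 or n == 0:
        return {
            "coarseness": coarseness,
            "contrast": 0.0,
            "busyness": 0.0,
            "complexity": 0.0,
            "strength": 0.0,
        }
    iz, pz, sz = i[nz], p[nz], s[nz]
    di = iz[:, None] - iz[None, :]
    contrast = float(
        (pz[:, None] * pz[None, :] * di**2).sum() / (ngp * (ngp - 1)) * (s.sum() / n)
    )
    denom_busy = float(np.abs(iz[:, None] * pz[:, None] - iz[None, :] * pz[None, :]).sum())
    busyness = ps / denom_busy if denom_busy > 0 else 0.0
    complexity = float(
        (
            np.abs(di)
            * (pz[:, None] * sz[:, None] + pz[None, :] * sz[None, :])
            / (pz[:, None] + pz[None, :])
        ).sum()
        / n
    )
    s_total = float(s.sum())
    strength = (
        float(((pz[:, None] + pz[None, :]) * di**2).sum()) / s_total if s_total > 0 else 0.0
    )
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": float(busyness),
        "complexity": complexity,
        "strength": strength,
    }


def texture_features(q: QuantizedROI) -> dict[str, dict[str, float]]:
    """All 43 texture feature values for one quantized ROI, keyed by family."""
    return {
        "global": global_features(q),
        "glcm": glcm_features(q),
        "glrlm": glrlm_features(q),
        "glszm": glszm_features(q),
        "ngtdm": ngtdm_features(q),
    }


# ---------------------------------------------------------------------------
# non-texture (shape) features
# ---------------------------------------------------------------------------


def nontexture_features(mask: np.ndarray, spacing) -> dict[str, float]:
    """Volume (mm^3), longest diameter (mm), solidity and eccentricity of a mask.

    * volume: voxel count x voxel volume;
    * size: maximum pairwise physical distance between surface-voxel centres;
    * solidity: mask volume / convex-hull volume, the hull taken over voxel
      corner points so a filled box scores exactly 1;
    * eccentricity: sqrt(1 - lmin/lmax) from the eigenvalues of the mask's
      second-moment matrix (voxel centres plus the per-voxel box moment), 0
      for a sphere.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    spacing = np.asarray(spacing, dtype=np.float64)
    voxel_volume = float(np.prod(spacing))
    n = int(mask.sum())
    volume = n * voxel_volume

    coords = np.argwhere(mask) * spacing

    surface = mask & ~ndimage.binary_erosion(mask)
    surf_pts = np.argwhere(surface) * spacing
    hull_pts = surf_pts
    if len(surf_pts) > 64:
        try:
            hull_pts = surf_pts[ConvexHull(surf_pts).vertices]
        except QhullError:
            pass
    if len(hull_pts) == 1:
        size = 0.0
    else:
        d2 = ((hull_pts[:, None, :] - hull_pts[None, :, :]) ** 2).sum(axis=-1)
        size = float(np.sqrt(d2.max()))

    # hull over voxel corners (surface voxels suffice: interior corners are inside)
    offsets = np.array(list(itertools.product((-0.5, 0.5), repeat=3))) * spacing
    corners = (surf_pts[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    try:
        hull_volume = ConvexHull(corners).volume
        solidity = volume / hull_volume if hull_volume > 0 else 1.0
    except QhullError:
        solidity = 1.0

    cov = np.cov(coords, rowvar=False) if n > 1 else np.zeros((3, 3))
    cov = np.atleast_2d(cov) + np.diag(spacing**2 / 12.0)
    eig = np.linalg.eigvalsh(cov)
    eccentricity = float(np.sqrt(max(0.0, 1.0 - eig[0] / eig[-1]))) if eig[-1] > 0 else 0.0

    return {
        "volume": volume,
        "size": size,
        "solidity": float(min(solidity, 1.0)),
        "eccentricity": eccentricity,
    }


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------


def extract_all(
    scans: dict[str, ScanVolume],
    rois: ROISet,
    grid: TextureParameterGrid | None = None,
    wavelet: str = "sym8",
    tissues=TISSUES,
    sequences=None,
) -> pd.Series:
    """Full feature vector for one scan (all sequences x tissues x grid points).

    Returns a Series indexed by canonical feature names
    ``seq|tissue|family|feature|params``; per tissue per sequence it holds
    4 non-texture + 43 x |grid| texture values.  Tissues whose mask is empty
    (natively or after resampling) are flagged with a warning and NaN values,
    never silent zeros.
    """
    grid = grid or TextureParameterGrid()
    sequences = tuple(sequences) if sequences is not None else tuple(sorted(scans))
    out: dict[str, float] = {}
    masks: dict[tuple[str, float | None], np.ndarray] = {}
    for seq in sequences:
        if seq not in scans:
            raise KeyError(f"scan for sequence {seq!r} missing")
        vol = scans[seq]
        # non-texture features from the native-resolution masks
        for tissue in tissues:
            native_mask = rois.mask(tissue)
            if not native_mask.any():
                warnings.warn(f"empty {tissue} mask: non-texture features missing", stacklevel=2)
                for feat in NONTEXTURE_FEATURES:
                    out[feature_name(seq, tissue, "nontexture", feat, "-")] = np.nan
            else:
                for feat, val in nontexture_features(native_mask, vol.spacing).items():
                    out[feature_name(seq, tissue, "nontexture", feat, "-")] = val

        filtered: dict[float, ScanVolume] = {}
        resampled: dict[tuple[float, float | None], ScanVolume] = {}
        for params in grid:
            if params.ratio not in filtered:
                filtered[params.ratio] = wavelet_bandpass_filter(vol, params.ratio, basis=wavelet)
            key = (params.ratio, params.scale)
            if key not in resampled:
                resampled[key] = resample_isotropic(filtered[params.ratio], params.scale)
            rvol = resampled[key]
            for tissue in tissues:
                mkey = (tissue, params.scale)
                if mkey not in masks:
                    masks[mkey] = resample_mask(rois.mask(tissue), rois.spacing, params.scale)
                rmask = masks[mkey]
                prefix_missing = not rmask.any()
                if prefix_missing:
                    warnings.warn(
                        f"empty {tissue} mask at scale {params.scale}: features missing",
                        stacklevel=2,
                    )
                    fam_values = {
                        fam: {feat: np.nan for feat in feats}
                        for fam, feats in (
                            ("global", GLOBAL_FEATURES),
                            ("glcm", GLCM_FEATURES),
                            ("glrlm", GLRLM_FEATURES),
                            ("glszm", GLSZM_FEATURES),
                            ("ngtdm", NGTDM_FEATURES),
                        )
                    }
                else:
                    q = quantize(rvol.data, rmask, params.quantizer, params.n_levels)
                    fam_values = texture_features(q)
                for fam, feats in fam_values.items():
                    for feat, val in feats.items():
                        out[feature_name(seq, tissue, fam, feat, params.tag)] = val
    return pd.Series(out)


class RadiomicsExtractor(BaseEstimator, TransformerMixin):
    """Transformer mapping cohort subjects to a feature table.

    ``transform`` accepts a list of :class:`~rtlipred.synthcohort.CohortSubject`
    and returns a DataFrame with a ``(subject_id, time_index)`` MultiIndex and
    one column per canonical feature name.

    Parameters
    ----------
    grid : TextureParameterGrid
        Texture parameter combinations (default: the full 240-point grid).
    wavelet : str
        Wavelet basis for the band-pass filter.
    tissues, sequences : tuples
        Which tissue masks and MRI sequences to extract from.
    time_indices : tuple of int or None
        Restrict extraction to these time indices (None = all scans).
    """

    def __init__(
        self,
        grid: TextureParameterGrid | None = None,
        wavelet: str = "sym8",
        tissues: tuple = TISSUES,
        sequences: tuple = SEQUENCES,
        time_indices: tuple | None = None,
    ):
        self.grid = grid
        self.wavelet = wavelet
        self.tissues = tissues
        self.sequences = sequences
        self.time_indices = time_indices

    def fit(self, X=None, y=None):
        return self

    def transform(self, subjects) -> pd.DataFrame:
        grid = self.grid or TextureParameterGrid()
        rows = {}
        for subj in subjects:
            for t in sorted(subj.scans):
                if self.time_indices is not None and t not in self.time_indices:
                    continue
                rows[(subj.subject_id, t)] = extract_all(
                    subj.scans[t],
                    subj.rois,
                    grid=grid,
                    wavelet=self.wavelet,
                    tissues=self.tissues,
                    sequences=self.sequences,
                )
        frame = pd.DataFrame.from_dict(rows, orient="index")
        frame.index = pd.MultiIndex.from_tuples(frame.index, names=["subject_id", "time_index"])
        return frame
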