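"""Core in-memory containers shared across the pipeline.

A :class:`ScanVolume` is one 3D MRI volume with physical voxel spacing and
cohort bookkeeping (subject, sequence, reverse-time index).  A
:class:`ROISet` bundles the three tissue masks used throughout: the manually
delineated medial temporal lobe (MTL) and the gray-/white-matter
sub-compartments within it.

Feature tables are plain :class:`pandas.DataFrame` objects with a
``(subject_id, time_index)`` MultiIndex and feature-name columns; the naming
scheme that encodes (sequence, tissue, family, feature, texture parameters)
into a column name lives here so every module parses it identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

#: canonical sequence tags: contrast-enhanced T1-weighted-like and T2-weighted-like
SEQUENCES = ("CET1w", "T2w")

#: canonical tissue tags
TISSUES = ("mtl", "gm", "wm")

#: feature families; everything except "nontexture" counts toward the 43 texture types
FAMILIES = ("global", "glcm", "glrlm", "glszm", "ngtdm", "nontexture")


@dataclass
class ScanVolume:
    """One 3D intensity volume with voxel spacing and cohort metadata.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities.
    spacing : tuple of float
        Physical voxel size in mm along each axis.
    sequence : str
        MRI sequence tag, one of :data:`SEQUENCES`.
    subject_id : str
        Cohort subject identifier.
    time_index : int
        Position in the subject's reverse time series, 1..N; N is the scan
        at which injury is confirmed (positives) or the last recorded scan
        (negatives).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    sequence: str = SEQUENCES[0]
    subject_id: str = ""
    time_index: int = 1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, spacing: tuple[float, float, float] | None = None) -> "ScanVolume":
        """Copy of this volume with new intensities (and optionally spacing)."""
        return replace(self, data=data, spacing=spacing if spacing is not None else self.spacing)


@dataclass
class ROISet:
    """Binary tissue masks on one scan grid.

    Invariants (checked): masks share one shape; ``gm`` and ``wm`` are
    disjoint subsets of ``mtl``.
    """

    mtl: np.ndarray
    gm: np.ndarray
    wm: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.mtl = np.asarray(self.mtl, dtype=bool)
        self.gm = np.asarray(self.gm, dtype=bool)
        self.wm = np.asarray(self.wm, dtype=bool)
        if not (self.mtl.shape == self.gm.shape == self.wm.shape):
            raise ValueError("ROI masks must share one shape")
        if np.any(self.gm & self.wm):
            raise ValueError("gray and white matter masks overlap")
        if np.any((self.gm | self.wm) & ~self.mtl):
            raise ValueError("gray/white matter masks must lie inside the MTL mask")
        self.spacing = tuple(float(s) for s in self.spacing)

    def mask(self, tissue: str) -> np.ndarray:
        if tissue not in TISSUES:
            raise KeyError(f"unknown tissue {tissue!r}; expected one of {TISSUES}")
        return getattr(self, tissue)

    def as_dict(self) -> Mapping[str, np.ndarray]:
        return {t: self.mask(t) for t in TISSUES}


# ---------------------------------------------------------------------------
# feature naming
# ---------------------------------------------------------------------------

_NAME_SEP = "|"


def format_params(ratio: float, scale: float | None, quantizer: str, n_levels: int) -> str:
    """Render one texture-parameter combination as a stable name fragment.

    ``scale=None`` means "native in-plane spacing" and renders as ``Snative``.
    """
    s = "native" if scale is None else f"{scale:g}"
    return f"R{ratio:g}_S{s}_{quantizer}_Ng{n_levels:d}"


def feature_name(sequence: str, tissue: str, family: str, feature: str, params: str) -> str:
    """Build the canonical column name ``seq|tissue|family|feature|params``.

    Non-texture features use ``params='-'``.
    """
    return _NAME_SEP.join((sequence, tissue, family, feature, params))


def parse_feature_name(name: str) -> dict[str, str]:
    """Split a canonical feature name back into its metadata fields."""
    parts = name.split(_NAME_SEP)
    if len(parts) != 5:
        raise ValueError(f"not a canonical feature name: {name!r}")
    seq, tissue, family, feat, params = parts
    return {
        "sequence": seq,
        "tissue": tissue,
        "family": family,
        "feature": feat,
        "params": params,
    }


def is_texture_feature(name: str) -> bool:
    """True for features of the 43-type texture inventory (global + matrix families)."""
    return parse_feature_name(name)["family"] != "nontexture"
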