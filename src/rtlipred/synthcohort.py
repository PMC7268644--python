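"""Synthetic longitudinal two-sequence MRI cohort generator.

Real cohorts for radiation-induced temporal lobe injury (RTLI) are hospital
data and not public, so the pipeline is exercised on synthetic cohorts that
emulate the relevant structure of the clinical data:

* anisotropic volumes (default 0.86 x 0.86 x 4.8 mm, i.e. 4 mm slices with a
  0.8 mm gap) for two sequences per scan (CET1-w-like and T2-w-like);
* per subject, a reverse time series of scans t1..tN, where N is the scan at
  which injury is confirmed (positives) or the last recorded scan
  (negatives);
* a medial-temporal-lobe (MTL) ROI with gray- and white-matter
  sub-compartments, shared across a subject's scans (perfect rigid
  co-registration is assumed);
* a *texture-only* class signal: positive subjects receive, inside the MTL,
  an added Gaussian random field with a shorter correlation length than the
  background noise.  Its amplitude grows as scans approach injury onset
  (effect sizes at N-1 >= N-2 >= N-3) and it changes local variance and
  spatial correlation without shifting mean intensity, so only texture
  features can separate the classes;
* class imbalance (default 40 positive vs 12 negative subjects, a scaled-down
  200:42).

Volumes are generated skull-free and bias-free, so no bias-field correction
or brain extraction is needed downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import ROISet, ScanVolume, SEQUENCES

POSITIVE = "RTLI+"
NEGATIVE = "RTLI-"

# mean tissue intensities per sequence: white matter bright on T1-like images,
# gray matter bright on T2-like images; "mix" covers MTL voxels outside gm/wm
_TISSUE_MEANS = {
    "CET1w": {"bg": 80.0, "gm": 100.0, "wm": 140.0, "mix": 118.0},
    "T2w": {"bg": 70.0, "gm": 120.0, "wm": 80.0, "mix": 102.0},
}
_NOISE_SD = 10.0
#: correlation length (mm) of the planted lesion field; shorter than the
#: default background noise so the signal is a texture change
_LESION_CORR_LENGTH = 1.5


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    ``effect_sizes[k-1]`` is the lesion-field amplitude (in units of the
    background noise SD) planted at scan N-k for positive subjects; it must be
    non-negative and non-increasing in k (the signal strengthens toward
    onset).  The confirmation scan N itself carries the N-1 amplitude.
    """

    n_positive: int = 40
    n_negative: int = 12
    n_scans_per_subject: int = 4
    volume_shape: tuple[int, int, int] = (64, 64, 32)
    voxel_spacing: tuple[float, float, float] = (0.86, 0.86, 4.8)
    effect_sizes: tuple[float, float, float] = (1.0, 0.5, 0.25)
    noise_correlation_length: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.volume_shape = tuple(int(v) for v in self.volume_shape)
        self.voxel_spacing = tuple(float(v) for v in self.voxel_spacing)
        self.effect_sizes = tuple(float(v) for v in self.effect_sizes)
        self.validate()

    def validate(self) -> None:
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("subject counts must be non-negative")
        if self.n_scans_per_subject < 4:
            raise ValueError("need n_scans_per_subject >= 4 so scans N-3..N exist")
        if len(self.volume_shape) != 3 or any(v <= 0 for v in self.volume_shape):
            raise ValueError(f"volume_shape must be three positive ints, got {self.volume_shape}")
        if len(self.voxel_spacing) != 3 or any(v <= 0 for v in self.voxel_spacing):
            raise ValueError(f"voxel_spacing must be three positive mm values, got {self.voxel_spacing}")
        if len(self.effect_sizes) != 3:
            raise ValueError("effect_sizes must give amplitudes for N-1, N-2, N-3")
        if any(e < 0 for e in self.effect_sizes):
            raise ValueError("effect_sizes must be non-negative")
        if any(a < b - 1e-12 for a, b in zip(self.effect_sizes, self.effect_sizes[1:])):
            raise ValueError("effect_sizes must be non-increasing with distance from onset")
        if self.noise_correlation_length <= 0:
            raise ValueError("noise_correlation_length must be positive")


@dataclass
class CohortSubject:
    """All in-memory data for one subject: scans indexed [time][sequence] plus ROIs."""

    subject_id: str
    label: str
    scans: dict[int, dict[str, ScanVolume]]
    rois: ROISet

    @property
    def n_scans(self) -> int:
        return len(self.scans)


@dataclass
class CohortManifest:
    """On-disk cohort index: one row per (subject, time_index, sequence)."""

    frame: pd.DataFrame
    root: Path

    COLUMNS = (
        "subject_id",
        "label",
        "time_index",
        "sequence",
        "volume_path",
        "roi_mtl_path",
        "roi_gm_path",
        "roi_wm_path",
    )

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        per_subj = self.frame.groupby("subject_id")["label"].nunique()
        if (per_subj > 1).any():
            raise ValueError("labels must be constant within subject")

    @property
    def subjects(self) -> list[str]:
        return sorted(self.frame["subject_id"].unique())

    @property
    def labels(self) -> pd.Series:
        return self.frame.groupby("subject_id")["label"].first()

    def save(self, path: Path | str) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def load(cls, path: Path | str) -> "CohortManifest":
        path = Path(path)
        return cls(pd.read_csv(path), root=path.parent)


def _correlated_field(rng: np.random.Generator, shape, spacing, corr_length_mm: float) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian random field with the given correlation length."""
    white = rng.standard_normal(shape)
    sigma_vox = [corr_length_mm / s for s in spacing]
    f = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="reflect")
    sd = f.std()
    if sd > 0:
        f = (f - f.mean()) / sd
    return f


def _make_rois(config: CohortConfig, rng: np.random.Generator) -> ROISet:
    """Ellipsoidal MTL with a white-matter core and a gray-matter shell.

    Radii scale with the physical extent of the volume and are jittered per
    subject so non-texture (shape) features vary across subjects but carry no
    label information.
    """
    shape = np.asarray(config.volume_shape, dtype=float)
    spacing = np.asarray(config.voxel_spacing, dtype=float)
    extent = shape * spacing

    center = shape / 2.0 + rng.uniform(-0.05, 0.05, size=3) * shape
    radii_mm = np.array([0.18 * extent[0], 0.18 * extent[1], 0.12 * extent[2]])
    radii_mm *= rng.uniform(0.85, 1.15, size=3)

    grids = np.meshgrid(*(np.arange(n) for n in config.volume_shape), indexing="ij")
    # normalized ellipsoidal radius in physical coordinates
    r2 = sum(((g - c) * s / rm) ** 2 for g, c, s, rm in zip(grids, center, spacing, radii_mm))
    r = np.sqrt(r2)

    mtl = r <= 1.0
    wm = r <= 0.55
    gm = (r > 0.55) & (r <= 0.85)
    if not (mtl.any() and wm.any() and gm.any()):
        raise ValueError(
            f"volume_shape {config.volume_shape} too small to hold non-empty tissue masks"
        )
    return ROISet(mtl=mtl, gm=gm, wm=wm, spacing=config.voxel_spacing)


def _effect_at(config: CohortConfig, time_index: int) -> float:
    """Lesion amplitude for a positive subject's scan at the given time index."""
    k = config.n_scans_per_subject - time_index
    if k == 0:
        return config.effect_sizes[0]
    if 1 <= k <= 3:
        return config.effect_sizes[k - 1]
    return 0.0


def generate_subject(
    config: CohortConfig,
    label: str,
    rng: np.random.Generator,
    subject_id: str = "sub000",
) -> CohortSubject:
    """Generate one subject: ``n_scans_per_subject`` two-sequence scans plus ROIs.

    Background = smooth per-tissue means + spatially correlated Gaussian noise.
    For ``label == 'RTLI+'`` an extra short-correlation-length field, scaled by
    the time-graded effect size and the noise SD and re-centred inside the MTL,
    is added to both sequences; mean ROI intensity is unchanged.
    """
    config.validate()
    if label not in (POSITIVE, NEGATIVE):
        raise ValueError(f"label must be {POSITIVE!r} or {NEGATIVE!r}, got {label!r}")
    rois = _make_rois(config, rng)

    base = {}
    for seq in SEQUENCES:
        means = _TISSUE_MEANS[seq]
        vol = np.full(config.volume_shape, means["bg"], dtype=np.float64)
        vol[rois.mtl] = means["mix"]
        vol[rois.gm] = means["gm"]
        vol[rois.wm] = means["wm"]
        # large-scale anatomical variation shared across the subject's scans
        slow = _correlated_field(rng, config.volume_shape, config.voxel_spacing, 4 * config.noise_correlation_length)
        base[seq] = vol + 2.0 * slow

    scans: dict[int, dict[str, ScanVolume]] = {}
    for t in range(1, config.n_scans_per_subject + 1):
        effect = _effect_at(config, t) if label == POSITIVE else 0.0
        per_seq: dict[str, ScanVolume] = {}
        for seq in SEQUENCES:
            noise = _NOISE_SD * _correlated_field(
                rng, config.volume_shape, config.voxel_spacing, config.noise_correlation_length
            )
            data = base[seq] + noise
            lesion = _correlated_field(
                rng, config.volume_shape, config.voxel_spacing, _LESION_CORR_LENGTH
            )
            if effect > 0:
                # standardize within the ROI so the planted amplitude really is
                # `effect` noise-SD units inside the lesion, with mean unchanged
                patch = lesion[rois.mtl]
                patch = patch - patch.mean()
                sd = patch.std()
                if sd > 0:
                    patch = patch / sd
                data = data.copy()
                data[rois.mtl] += effect * _NOISE_SD * patch
            per_seq[seq] = ScanVolume(
                data=data,
                spacing=config.voxel_spacing,
                sequence=seq,
                subject_id=subject_id,
                time_index=t,
            )
        scans[t] = per_seq
    return CohortSubject(subject_id=subject_id, label=label, scans=scans, rois=rois)


def simulate_cohort(config: CohortConfig) -> list[CohortSubject]:
    """Generate the full cohort in memory, deterministically from ``config.seed``."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    n_total = config.n_positive + config.n_negative
    children = ss.spawn(n_total)
    subjects = []
    for i in range(n_total):
        label = POSITIVE if i < config.n_positive else NEGATIVE
        sid = f"sub{i:03d}"
        subjects.append(generate_subject(config, label, np.random.default_rng(children[i]), sid))
    return subjects


def _affine(spacing) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def write_subject(subject: CohortSubject, outdir: Path) -> list[dict]:
    """Write one subject's volumes and masks as NIfTI; return manifest rows."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = _affine(subject.rois.spacing)
    roi_paths = {}
    for tissue in ("mtl", "gm", "wm"):
        p = outdir / f"{subject.subject_id}_roi_{tissue}.nii.gz"
        nib.save(nib.Nifti1Image(subject.rois.mask(tissue).astype(np.uint8), aff), p)
        roi_paths[tissue] = p
    rows = []
    for t in sorted(subject.scans):
        for seq, vol in subject.scans[t].items():
            p = outdir / f"{subject.subject_id}_t{t}_{seq}.nii.gz"
            nib.save(nib.Nifti1Image(vol.data.astype(np.float32), aff), p)
            rows.append(
                {
                    "subject_id": subject.subject_id,
                    "label": subject.label,
                    "time_index": t,
                    "sequence": seq,
                    "volume_path": str(p),
                    "roi_mtl_path": str(roi_paths["mtl"]),
                    "roi_gm_path": str(roi_paths["gm"]),
                    "roi_wm_path": str(roi_paths["wm"]),
                }
            )
    return rows


def generate_cohort(config: CohortConfig, outdir: Path | str) -> CohortManifest:
    """Generate the cohort and write NIfTI volumes, masks and a CSV manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []
    for subject in simulate_cohort(config):
        try:
            rows.extend(write_subject(subject, outdir / subject.subject_id))
        except OSError as exc:  # surface the offending path
            raise OSError(f"failed writing subject {subject.subject_id} under {outdir}: {exc}") from exc
    frame = pd.DataFrame(rows, columns=list(CohortManifest.COLUMNS))
    manifest = CohortManifest(frame=frame, root=outdir)
    manifest.save(outdir / "manifest.csv")
    return manifest


def _load_volume(path: str) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def load_cohort(manifest: CohortManifest | Path | str) -> list[CohortSubject]:
    """Read a written cohort back into :class:`CohortSubject` objects."""
    if not isinstance(manifest, CohortManifest):
        manifest = CohortManifest.load(manifest)
    subjects = []
    for sid, grp in manifest.frame.groupby("subject_id", sort=True):
        label = grp["label"].iloc[0]
        first = grp.iloc[0]
        masks = {}
        spacing = None
        for tissue in ("mtl", "gm", "wm"):
            path = first[f"roi_{tissue}_path"]
            try:
                data, spacing = _load_volume(path)
            except Exception as exc:
                raise OSError(f"failed reading ROI {path}: {exc}") from exc
            masks[tissue] = data > 0.5
        rois = ROISet(spacing=spacing, **masks)
        scans: dict[int, dict[str, ScanVolume]] = {}
        for _, row in grp.iterrows():
            try:
                data, vspacing = _load_volume(row["volume_path"])
            except Exception as exc:
                raise OSError(f"failed reading volume {row['volume_path']}: {exc}") from exc
            t = int(row["time_index"])
            scans.setdefault(t, {})[row["sequence"]] = ScanVolume(
                data=data,
                spacing=vspacing,
                sequence=row["sequence"],
                subject_id=sid,
                time_index=t,
            )
        subjects.append(CohortSubject(subject_id=sid, label=label, scans=scans, rois=rois))
    return subjects
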