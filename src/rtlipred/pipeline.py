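"""End-to-end orchestration: simulate -> preprocess -> extract -> select -> train/eval.

Two entry points:

* :func:`run_study` executes the whole analysis in memory on a synthetic
  cohort and returns a :class:`StudyResult`; it is what the tests and the
  reproduction script drive.
* :func:`run_pipeline` is the file-based, resumable variant behind the CLI:
  each stage reads only the previous stage's artifacts (NIfTI / CSV / JSON),
  embeds a hash of its configuration section in the output directory, and is
  skipped on re-run when the hash and outputs are unchanged.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import SEQUENCES, TISSUES
from .model import (
    EvalResult,
    ModelDataset,
    SEQUENCE_SETS,
    TOPK_DEFAULT,
    assemble_model_dataset,
    evaluate_model,
    select_columns,
    split_train_test,
)
from .preprocess import HistogramNormalizer
from .select import Bootstrap632Ranker, ReliefFSelector, screen_candidates
from .synthcohort import CohortConfig, CohortManifest, generate_cohort, load_cohort, simulate_cohort, write_subject
from .texture import RadiomicsExtractor, TextureParameterGrid

log = logging.getLogger("rtlipred")


def _derived_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds below 2**31."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def normalize_cohort(subjects, percentiles=None) -> None:
    """In-place histogram standardization, fitted per (sequence, time point)."""
    kwargs = {} if percentiles is None else {"percentiles": percentiles}
    time_indices = sorted({t for s in subjects for t in s.scans})
    for seq in SEQUENCES:
        for t in time_indices:
            vols = [s.scans[t][seq] for s in subjects if t in s.scans and seq in s.scans[t]]
            if len(vols) < 2:
                continue
            norm = HistogramNormalizer(**kwargs).fit(vols)
            for s in subjects:
                if t in s.scans and seq in s.scans[t]:
                    s.scans[t][seq] = norm.transform_volume(s.scans[t][seq])


def cohort_labels(subjects) -> pd.Series:
    return pd.Series({s.subject_id: s.label for s in subjects}).sort_index()


@dataclass
class ModelRun:
    """Selection diagnostics and evaluation results for one model index."""

    k: int
    screened: list[str]
    ranking: list[str]
    selected: list[str]
    results: dict[int, EvalResult]
    test_scores: np.ndarray
    test_labels: np.ndarray
    relief_weights: pd.Series | None = None
    scores_0632: pd.Series | None = None


@dataclass
class StudyResult:
    """Outcome of one in-memory end-to-end run."""

    config: CohortConfig
    train_subjects: list[str]
    test_subjects: list[str]
    models: dict[int, ModelRun]
    n_features: int
    n_texture_features: int


def select_and_rank(
    X_train: pd.DataFrame,
    y_train,
    relief_k: int = 10,
    B: int = 200,
    top_n: int = 20,
    seed: int = 0,
    families=None,
):
    """Relief screen (2 per parameter set) then 0.632+ ranking to ``top_n``.

    With ``families`` restricted to non-texture the relief screen is skipped
    and the non-texture features are ranked directly (the shape-only baseline
    model).  Returns (screened texture features, fitted ranker, relief
    weights or None).
    """
    if families is not None and tuple(families) == ("nontexture",):
        candidates = list(select_columns(X_train, families=("nontexture",)).columns)
        screened: list[str] = []
        relief = None
    else:
        relief = ReliefFSelector(n_neighbors=relief_k).fit(X_train, y_train)
        screened = relief.selected_
        candidates = screen_candidates(X_train, screened)
    ranker = Bootstrap632Ranker(B=B, top_n=min(top_n, len(candidates)), random_state=seed).fit(
        X_train[candidates], y_train
    )
    return screened, ranker, (relief.weights_ if relief is not None else None)


def run_study(
    config: CohortConfig,
    grid: TextureParameterGrid | None = None,
    tissue: str = "mtl",
    sequences: tuple = SEQUENCES,
    model_ks: tuple = (1, 2, 3),
    topk_list: tuple = (20,),
    top_n: int = 20,
    relief_k: int = 10,
    B_select: int = 200,
    B_eval: int = 200,
    n_estimators: int = 300,
    fraction: float = 0.8,
    wavelet: str = "sym8",
    normalize: bool = True,
    families=None,
    subjects=None,
    features=None,
) -> StudyResult:
    """Simulate a cohort and run the full pipeline in memory.

    Pre-generated ``subjects`` (and optionally their ``features`` table) may
    be passed to reuse expensive stages across calls; they must match
    ``config``.
    """
    grid = grid or TextureParameterGrid()
    seeds = _derived_seeds(config.seed, 4)
    if subjects is None:
        subjects = simulate_cohort(config)
        if normalize:
            normalize_cohort(subjects)
    labels = cohort_labels(subjects)

    N = config.n_scans_per_subject
    if features is None:
        t0 = time.perf_counter()
        extractor = RadiomicsExtractor(
            grid=grid,
            wavelet=wavelet,
            tissues=(tissue,),
            sequences=tuple(sequences),
            time_indices=tuple(range(N - 3, N)),
        )
        features = extractor.transform(subjects)
        log.info("extracted %d features x %d rows in %.1fs", features.shape[1], len(features), time.perf_counter() - t0)
    n_texture = len(select_columns(features, families=("global", "glcm", "glrlm", "glszm", "ngtdm")).columns)

    train_ids, test_ids = split_train_test(labels.index, labels, fraction=fraction, seed=seeds[0])

    models: dict[int, ModelRun] = {}
    for k in model_ks:
        ds = assemble_model_dataset(features, labels, k, n_scans=N)
        train_ds = ds.restrict(train_ids)
        test_ds = ds.restrict(test_ids)
        screened, ranker, weights = select_and_rank(
            train_ds.X,
            train_ds.y,
            relief_k=relief_k,
            B=B_select,
            top_n=top_n,
            seed=seeds[1],
            families=families,
        )
        results: dict[int, EvalResult] = {}
        scores_top = None
        for kk in sorted(set(topk_list)):
            feats = ranker.ranking_[: min(kk, len(ranker.ranking_))]
            res, scores = evaluate_model(
                ModelDataset(k, train_ds.X[feats], train_ds.y, train_ds.subjects),
                ModelDataset(k, test_ds.X[feats], test_ds.y, test_ds.subjects),
                n_estimators=n_estimators,
                seed=seeds[2],
                B=B_eval,
                model_k=k,
                tissue=tissue,
                sequences=tuple(sequences),
                top_k=kk,
            )
            results[kk] = res
            scores_top = scores
        models[k] = ModelRun(
            k=k,
            screened=screened,
            ranking=ranker.ranking_,
            selected=ranker.selected_,
            results=results,
            test_scores=scores_top,
            test_labels=test_ds.y,
            relief_weights=weights,
            scores_0632=ranker.scores_,
        )
    return StudyResult(
        config=config,
        train_subjects=list(train_ids),
        test_subjects=list(test_ids),
        models=models,
        n_features=features.shape[1],
        n_texture_features=n_texture,
    )


def comparison_grid(
    features: pd.DataFrame,
    labels: pd.Series,
    n_scans: int,
    model_ks: tuple = (1, 2, 3),
    topk_list: tuple = TOPK_DEFAULT,
    tissues: tuple = TISSUES,
    sequence_sets: tuple = SEQUENCE_SETS,
    relief_k: int = 10,
    B_select: int = 200,
    B_eval: int = 200,
    top_n: int = 20,
    n_estimators: int = 300,
    fraction: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Full factorial evaluation: models x top-k x tissues x sequence sets.

    One subject-level split (fixed seed) is shared by all cells; selection is
    re-run per (model, tissue, sequence set) on the training rows.  Returns a
    tidy frame with one row per cell (3 x 5 x 3 x 3 = 135 by default).
    """
    seeds = _derived_seeds(seed, 4)
    train_ids, test_ids = split_train_test(labels.index, labels, fraction=fraction, seed=seeds[0])
    rows = []
    for tissue in tissues:
        for seqset in sequence_sets:
            sub = select_columns(features, tissue=tissue, sequences=seqset)
            for k in model_ks:
                ds = assemble_model_dataset(sub, labels, k, n_scans=n_scans)
                train_ds = ds.restrict(train_ids)
                test_ds = ds.restrict(test_ids)
                _, ranker, _ = select_and_rank(
                    train_ds.X, train_ds.y, relief_k=relief_k, B=B_select, top_n=top_n, seed=seeds[1]
                )
                for kk in topk_list:
                    feats = ranker.ranking_[: min(kk, len(ranker.ranking_))]
                    res, _ = evaluate_model(
                        ModelDataset(k, train_ds.X[feats], train_ds.y, train_ds.subjects),
                        ModelDataset(k, test_ds.X[feats], test_ds.y, test_ds.subjects),
                        n_estimators=n_estimators,
                        seed=seeds[2],
                        B=B_eval,
                        model_k=k,
                        tissue=tissue,
                        sequences=tuple(seqset),
                        top_k=kk,
                    )
                    rows.append(
                        {
                            "model": k,
                            "tissue": tissue,
                            "sequences": "+".join(seqset),
                            "topk": kk,
                            "mean_auc": res.mean_auc,
                            "ci_lo": res.ci_lo,
                            "ci_hi": res.ci_hi,
                            "n_train": res.n_train,
                            "n_test": res.n_test,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file-based staged pipeline
# ---------------------------------------------------------------------------


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    """Single-file configuration for the staged pipeline."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    normalize: bool = True
    grid: TextureParameterGrid = field(default_factory=TextureParameterGrid)
    wavelet: str = "sym8"
    tissue: str = "mtl"
    sequences: tuple = SEQUENCES
    relief_k: int = 10
    B_select: int = 200
    top_n: int = 20
    model_ks: tuple = (1, 2, 3)
    topk_list: tuple = (20,)
    n_estimators: int = 300
    B_eval: int = 200
    fraction: float = 0.8
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortConfig(**d["cohort"])
        if "grid" in d:
            g = {k: tuple(v) for k, v in d["grid"].items()}
            d["grid"] = TextureParameterGrid(**g)
        for key in ("sequences", "model_ks", "topk_list"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def section(self, *names) -> dict:
        d = asdict(self)
        return {k: d[k] for k in names}


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _stage_done(outdir: Path, stage: str, h: str, outputs: list[Path]) -> bool:
    f = outdir / f"{stage}.hash"
    return f.exists() and f.read_text().strip() == h and all(p.exists() for p in outputs)


def _mark_stage(outdir: Path, stage: str, h: str) -> None:
    (outdir / f"{stage}.hash").write_text(h)


STAGES = ("simulate", "preprocess", "extract", "select", "train_eval")


def run_pipeline(config: PipelineConfig, outdir, until: str | None = None) -> dict:
    """Run the stages in order with per-stage artifacts and hash-based skipping.

    ``until`` stops after the named stage (one of ``STAGES``); the run report
    (written to ``report.json``) is produced only by a full run.  Re-running
    with an unchanged config recomputes nothing; a stage failure raises
    :class:`PipelineError` naming the stage.
    """
    if until is not None and until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; expected one of {STAGES}")
    last = STAGES.index(until) if until is not None else len(STAGES) - 1
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    def stage(name, h, outputs, fn):
        if STAGES.index(name) > last:
            return
        if _stage_done(outdir, name, h, outputs):
            log.info("stage %s: up to date, skipped", name)
            report["stages"][name] = {"skipped": True}
            return
        t0 = time.perf_counter()
        try:
            fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        _mark_stage(outdir, name, h)
        report["stages"][name] = {"skipped": False, "seconds": round(time.perf_counter() - t0, 2)}
        log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)

    seeds = _derived_seeds(config.seed, 4)

    # -- simulate ----------------------------------------------------------
    cohort_dir = outdir / "cohort"
    h_sim = _hash(config.section("cohort"))
    stage("simulate", h_sim, [cohort_dir / "manifest.csv"], lambda: generate_cohort(config.cohort, cohort_dir))

    # -- preprocess --------------------------------------------------------
    norm_dir = outdir / "normalized"
    h_pre = _hash([h_sim, config.section("normalize")])

    def do_preprocess():
        subjects = load_cohort(cohort_dir / "manifest.csv")
        if config.normalize:
            normalize_cohort(subjects)
        rows = []
        for s in subjects:
            rows.extend(write_subject(s, norm_dir / s.subject_id))
        frame = pd.DataFrame(rows, columns=list(CohortManifest.COLUMNS))
        CohortManifest(frame=frame, root=norm_dir).save(norm_dir / "manifest.csv")

    stage("preprocess", h_pre, [norm_dir / "manifest.csv"], do_preprocess)

    # -- extract -----------------------------------------------------------
    features_csv = outdir / "features.csv"
    h_ext = _hash([h_pre, config.section("grid", "wavelet", "tissue", "sequences")])

    def do_extract():
        subjects = load_cohort(norm_dir / "manifest.csv")
        N = config.cohort.n_scans_per_subject
        extractor = RadiomicsExtractor(
            grid=config.grid,
            wavelet=config.wavelet,
            tissues=(config.tissue,),
            sequences=config.sequences,
            time_indices=tuple(range(N - 3, N)),
        )
        extractor.transform(subjects).to_csv(features_csv)

    stage("extract", h_ext, [features_csv], do_extract)

    # -- select ------------------------------------------------------------
    selected_json = outdir / "selected.json"
    h_sel = _hash([h_ext, config.section("relief_k", "B_select", "top_n", "model_ks", "fraction", "seed")])

    def do_select():
        features = pd.read_csv(features_csv, index_col=[0, 1])
        manifest = CohortManifest.load(norm_dir / "manifest.csv")
        labels = manifest.labels
        train_ids, test_ids = split_train_test(labels.index, labels, fraction=config.fraction, seed=seeds[0])
        out = {"train_subjects": list(train_ids), "test_subjects": list(test_ids), "models": {}}
        for k in config.model_ks:
            ds = assemble_model_dataset(features, labels, k, n_scans=config.cohort.n_scans_per_subject)
            train_ds = ds.restrict(train_ids)
            screened, ranker, weights = select_and_rank(
                train_ds.X, train_ds.y, relief_k=config.relief_k, B=config.B_select,
                top_n=config.top_n, seed=seeds[1],
            )
            out["models"][str(k)] = {
                "n_screened": len(screened),
                "screened": screened,
                "ranking": ranker.ranking_,
                "selected": ranker.selected_,
                "scores_0632": {n: float(ranker.scores_[n]) for n in ranker.ranking_},
                "relief_weights_top": {
                    n: float(weights[n]) for n in (weights.nlargest(20).index if weights is not None else [])
                },
            }
        selected_json.write_text(json.dumps(out, indent=1))

    stage("select", h_sel, [selected_json], do_select)

    # -- train/eval --------------------------------------------------------
    results_csv = outdir / "results.csv"
    h_fit = _hash([h_sel, config.section("n_estimators", "B_eval", "topk_list")])

    def do_train_eval():
        features = pd.read_csv(features_csv, index_col=[0, 1])
        manifest = CohortManifest.load(norm_dir / "manifest.csv")
        labels = manifest.labels
        sel = json.loads(selected_json.read_text())
        rows = []
        for k in config.model_ks:
            ds = assemble_model_dataset(features, labels, k, n_scans=config.cohort.n_scans_per_subject)
            train_ds = ds.restrict(sel["train_subjects"])
            test_ds = ds.restrict(sel["test_subjects"])
            ranking = sel["models"][str(k)]["ranking"]
            for kk in config.topk_list:
                feats = ranking[: min(kk, len(ranking))]
                res, _ = evaluate_model(
                    ModelDataset(k, train_ds.X[feats], train_ds.y, train_ds.subjects),
                    ModelDataset(k, test_ds.X[feats], test_ds.y, test_ds.subjects),
                    n_estimators=config.n_estimators,
                    seed=seeds[2],
                    B=config.B_eval,
                    model_k=k,
                    tissue=config.tissue,
                    sequences=config.sequences,
                    top_k=kk,
                )
                rows.append(
                    {
                        "model": k,
                        "tissue": config.tissue,
                        "sequences": "+".join(config.sequences),
                        "topk": kk,
                        "mean_auc": res.mean_auc,
                        "ci_lo": res.ci_lo,
                        "ci_hi": res.ci_hi,
                        "n_train": res.n_train,
                        "n_test": res.n_test,
                    }
                )
        pd.DataFrame(rows).to_csv(results_csv, index=False)

    stage("train_eval", h_fit, [results_csv], do_train_eval)

    # -- report ------------------------------------------------------------
    if last < len(STAGES) - 1:
        return report
    features = pd.read_csv(features_csv, index_col=[0, 1], nrows=1)
    sel = json.loads(selected_json.read_text())
    n_texture = sum(1 for c in features.columns if not c.split("|")[2] == "nontexture")
    report.update(
        {
            "n_features": features.shape[1],
            "n_texture_features_per_tissue": n_texture // len(config.sequences),
            "n_screened": {k: v["n_screened"] for k, v in sel["models"].items()},
            "results": pd.read_csv(results_csv).to_dict(orient="records"),
        }
    )
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    return report
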