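# rtlipred

Longitudinal MRI radiomics for **early prediction of radiation-induced
temporal lobe injury (RTLI)** in nasopharyngeal-carcinoma patients after
radiotherapy.

RTLI is a late, progressive complication of head-and-neck radiotherapy that
conventional MRI only reveals once white-matter damage is established. This
package implements the full radiomics analysis chain that addresses the
problem prospectively — predicting, from a patient's follow-up scans *before*
injury is visible, whether injury will be confirmed — and exercises it
end-to-end on synthetic longitudinal cohorts with a planted, time-graded
texture signal, since cohorts of this kind are hospital data and not public.

## What it computes

For each subject with follow-up scans t1..tN (two sequences: CET1-w-like and
T2-w-like; N = scan at injury confirmation for positives), the pipeline:

1. **simulates** a cohort (anisotropic NIfTI volumes, MTL/gray/white masks,
   CSV manifest) with class imbalance and a texture-only signal that
   strengthens toward onset;
2. **standardizes intensities** with two-step histogram-landmark
   normalization (fit per sequence per time point) and, where needed,
   segments gray/white matter with a two-class HMRF-EM;
3. **extracts features**: per tissue per sequence, 4 shape features plus
   43 texture features (global moments, GLCM, GLRLM, GLSZM, NGTDM) for every
   point of a texture-parameter grid — wavelet band-pass ratio R × isotropic
   scale s × quantizer × gray levels Ng; the default 5 × 6 × 2 × 4 grid
   yields 43 × 240 = 10,320 texture values per tissue per sequence;
4. **selects features** in two stages: a ReliefF screen keeping the two
   top-weighted features per parameter set (480 on the default grid), then a
   univariate **0.632+ bootstrap AUC** ranking to the top 20,

       AUC_0.632+ = (1/B) Σ_b [(1 − a(b))·AUC(X,X) + a(b)·AUC′(X*b, X*b(0))],
       AUC′ = max{0.5, AUC(X*b, X*b(0))},  a(b) = 0.632/(1 − 0.368·R(b)),

   with R(b) the relative overfitting rate (1 if the out-of-bag AUC ≤ 0.5;
   (AUC(X,X) − AUC(X*b,X*b(0)))/(AUC(X,X) − 0.5) if 2 > AUC(X,X)/AUC′ > 1;
   else 0), resampling subjects with class stratification;
5. **trains three random-forest models** — model k predicts injury from the
   scan k steps before confirmation (k = 1, 2, 3), negatives contributing
   their last three scans to every model — on an 80/20 subject-level
   stratified split, and reports test AUC with a bootstrap 95% CI, including
   a full comparison grid over models × top-k ∈ {1, 5, 10, 15, 20} × tissues
   × sequence sets.

The package is organised as scikit-learn-style estimators
(`HistogramNormalizer`, `HmrfSegmenter`, `RadiomicsExtractor`,
`ReliefFSelector`, `Bootstrap632Ranker`) with thin functional wrappers, plus
a `rtli` CLI for the staged, resumable file-based pipeline.

## Worked example

```python
from rtlipred import CohortConfig, run_study
from rtlipred.texture import TextureParameterGrid

grid = TextureParameterGrid(ratios=(0.5, 1.0, 2.0), scales=(2.0, 3.0),
                            quantizers=("equalprob", "uniform"), gray_levels=(8, 16))
cfg = CohortConfig(n_positive=40, n_negative=12, volume_shape=(48, 48, 24), seed=1001)
res = run_study(cfg, grid=grid, B_select=200, B_eval=200, n_estimators=200, top_n=20)
for k in (1, 2, 3):
    r = res.models[k].results[20]
    print(f"model {k} (scan N-{k}): test AUC {r.mean_auc:.3f} "
          f"(95% CI {r.ci_lo:.3f}-{r.ci_hi:.3f})")
```

prints

```
model 1 (scan N-1): test AUC 0.939 (95% CI 0.805-1.000)
model 2 (scan N-2): test AUC 0.722 (95% CI 0.486-0.944)
model 3 (scan N-3): test AUC 0.719 (95% CI 0.430-0.910)
```

The cohort plants a texture-only lesion signal of 1.0, 0.5 and 0.25
noise-SD units at scans N−1, N−2 and N−3, so prediction is easiest closest
to onset: model 1 is clearly above chance, models 2 and 3 progressively
weaker — the expected time-graded pattern. Single-cohort CIs are wide (the
scaled test set holds ~19 rows); the test suite averages this experiment
over 10 cohorts. `res.models[1].selected` lists the top-20 features, all of
texture families here because only texture carries label information.

The same analysis runs from the shell on file artifacts:

```sh
rtli run --config config.yaml --out runs/demo     # simulate → ... → results.csv
rtli grid --features runs/demo/features.csv \
          --manifest runs/demo/normalized/manifest.csv --out grid.csv
```

Each stage writes its artifacts (NIfTI, CSV, JSON) and a config hash;
re-running skips completed stages.

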