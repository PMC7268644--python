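# Methods

`rtlipred` implements a longitudinal MRI radiomics analysis for early
prediction of radiation-induced temporal lobe injury (RTLI) after
nasopharyngeal-carcinoma radiotherapy, exercised end-to-end on synthetic
cohorts because the clinical cohorts this kind of analysis is run on are not
public. This note records the models, the defaults and why, what the
synthetic data do and do not emulate, and the numerical conventions.

## Problem setup

Each subject has a reverse time series of follow-up scans t1..tN in two MRI
sequences (CET1-w-like and T2-w-like). For RTLI-positive subjects, N is the
scan at which injury is confirmed; for negatives, the last recorded scan.
Three classifiers predict injury before confirmation: model k (k = 1, 2, 3)
uses each positive subject's scan at N−k. Negative subjects contribute their
scans at N−1, N−2 and N−3 to all three models, which softens the class
imbalance (the clinical setting is roughly 200 positives vs 42 negatives;
the scaled default is 40 vs 12).

## Synthetic cohort generator

Volumes are anisotropic (default 0.86 × 0.86 × 4.8 mm, i.e. 4 mm slices with
a 0.8 mm gap) and skull-free and bias-free, so no brain extraction or
bias-field correction stage is needed. Each subject gets one ellipsoidal
medial-temporal-lobe (MTL) mask with a white-matter core and a gray-matter
shell, shared across that subject's scans (perfect rigid co-registration is
assumed; registration is outside the pipeline's scope). Tissue means differ
per sequence (white matter bright on T1-like, gray matter bright on
T2-like); on top sit a smooth per-subject anatomical field and spatially
correlated Gaussian noise (SD 10, correlation length 3 mm).

The class signal is texture-only by construction: positive subjects receive,
inside the MTL, an added Gaussian random field with a *shorter* correlation
length (1.5 mm) than the background noise. The field is standardized within
the ROI so its amplitude is exactly `effect_sizes[k−1]` noise-SD units at
scan N−k, and it is mean-centred, so mean ROI intensity carries no label
information and only texture (local variance and spatial correlation) can
separate the classes. Effect sizes default to (1.0, 0.5, 0.25) at
(N−1, N−2, N−3): the signal strengthens as scans approach onset. The
confirmation scan N carries the N−1 amplitude. No published estimate of the
clinical texture effect size at any time point exists; these amplitudes are
free parameters of the simulation, not estimates of the clinical signal.

What the generator does **not** emulate: lesion morphology (finger-like
edema, cysts, necrosis), bias fields, skulls, registration error, scanner
drift, or partial-volume effects. Passing tests therefore demonstrate that
the pipeline recovers a planted, time-graded texture signal under realistic
geometry and imbalance — not that it would reach any particular AUC on
clinical data.

## Preprocessing

**Intensity standardization** is the two-step learn/transform histogram
method: landmark intensities at fixed percentiles (deciles plus 1%/99%
tails by default; the landmark set is a convention, configurable) are
anchored affinely so the extreme landmarks hit a fixed output range (0-100),
averaged across training volumes, and each volume is then mapped through its
own landmarks by a piecewise-linear monotone interpolation, clipped to the
range. The model is fitted separately per sequence and per follow-up time
point. The map is monotone by construction and idempotent up to
interpolation error on the standard scale.

**Tissue segmentation** within an ROI uses a two-class Gaussian hidden
Markov random field fitted by hard EM: each iteration relabels all ROI
voxels synchronously by minimizing Gaussian negative log-likelihood plus
β × (number of disagreeing 6-neighbours), then re-estimates class means and
variances from the hard labels. Initialization is a median split of the ROI
intensities, so the algorithm is deterministic without a seed; classes are
reported in ascending-mean order to remove label-permutation ambiguity;
β = 0 reduces to classification EM on a two-component mixture. A constant
ROI converges immediately with one empty class and a degenerate flag. The
synthetic pipeline uses the generator's ground-truth masks by default; the
segmenter is provided for workflows that must derive gray/white compartments
from intensities.

## Texture features

Per texture-parameter combination — wavelet band-pass ratio R, isotropic
scale s, quantizer, gray-level count Ng — the processing order is: wavelet
filter → isotropic resample (trilinear; nearest-neighbour for masks) →
quantize → features. The order is a convention. 43 feature types are
computed per combination: 3 global histogram moments (variance, skewness,
excess kurtosis of the quantized ROI), 9 GLCM, 13 GLRLM, 13 GLSZM and 5
NGTDM features. The default grid is 5 ratios {1/2, 2/3, 1, 3/2, 2} ×
6 scales {1, 2, 3, 4, 5 mm, native in-plane} × 2 quantizers
{equal-probability, uniform} × 4 gray-level counts {8, 16, 32, 64} = 240
combinations → 10,320 texture values per tissue per sequence, plus 4
non-texture shape features (volume, longest diameter, solidity,
eccentricity) computed once per tissue from the native-resolution mask. All
grid axes are configurable; the global moments are computed per combination
(on each filtered, resampled, quantized ROI) to keep the 43-per-combination
inventory uniform even though two of them vary little across quantizers.

Conventions that matter for reproducibility:

* the wavelet filter weights the six mixed sub-bands of a one-level 3D DWT
  (default basis `sym8`) by R, the LLL/HHH sub-bands by 1, and renormalizes
  by the mean weight, so R = 1 is an exact identity and the filter is linear;
* GLCM pools the 13 unique 3D directions at distance 1, symmetrized and
  normalized; GLRLM pools maximal same-level runs over the same 13
  directions; GLSZM zones are 26-connected; NGTDM uses 26-neighbourhood
  means restricted to the ROI;
* matrices are built only from voxels/pairs/zones fully inside the ROI, and
  all matrix features are translation invariant;
* degenerate inputs produce documented constants, never NaN: a single-level
  ROI gives GLCM energy 1, contrast 0, correlation 0 (the 0/0 case),
  run/zone variation measures 0, and NGTDM coarseness capped at 1e6; a GLCM
  with no valid pair collapses to a point mass at the modal level (smallest
  on ties);
* equal-probability quantization places bin edges at ROI quantiles k/Ng
  (linear interpolation); uniform quantization uses equal-width bins over
  the ROI's [min, max]; a constant ROI maps to level 1 with a degenerate
  flag.

Every matrix feature is verified against an independent brute-force
implementation (naive enumeration of pairs, runs, zones and neighbourhoods)
on random ROIs to 1e−10 relative tolerance.

## Feature selection

**Stage 1 — ReliefF screen.** Features are scaled to [0, 1]; each instance's
k = 10 nearest hits and misses (Euclidean distance, ties broken by instance
index) contribute the mean absolute feature difference to the feature's
weight (misses positive, hits negative), averaged over all instances.
Within each texture-parameter combination the two top-weighted texture
features are kept — 480 on the default grid. The screen runs on training
subjects only, so no information from the held-out 20% enters selection.

**Stage 2 — 0.632+ bootstrap AUC ranking.** Subjects are resampled B = 1000
times (B = 200 in the scaled studies) with class stratification — each class
resampled to its own size, the "imbalance-adjusted" reading that preserves
prevalence in every in-bag set. Each candidate feature is scored
univariately: the feature value is the decision score, oriented so the
apparent AUC is ≥ 0.5 (a univariate scorer is the only choice that needs no
additional modeling assumptions at this stage). Per replicate,
AUC′ = max{0.5, out-of-bag AUC}; the relative overfitting rate is R = 1 if
the out-of-bag AUC ≤ 0.5, (apparent − oob)/(apparent − 0.5) if
2 > apparent/AUC′ > 1, else 0, clipped to [0, 1]; the weight is
a = 0.632/(1 − 0.368 R); the feature's score is the mean over replicates of
(1 − a)·apparent + a·AUC′. When the apparent AUC is ≤ 0.5 the middle branch
would divide by a non-positive number, so only the first/third branches
apply. Features are ranked descending (ties by name) and the top 20 kept.

Because the per-parameter-set screen can *only* return texture features, the
ranking stage considers the screened texture features together with all
non-texture features in the table. A texture-only top-20 is therefore an
outcome of the data, not of the plumbing.

## Models and evaluation

The split is at subject level, stratified by label, 80/20, before any
selection. Classifiers are random forests (500 trees by default, 200 in the
scaled studies; √p features per split; unlimited depth — no hyperparameters
are prescribed beyond these conventions). Training rows are sorted
canonically by (subject, time index) before fitting so results do not depend
on incidental row order. Test performance is the AUC of the positive-class
probability, with mean and 95% percentile CI over B = 1000 (scaled: 200)
class-stratified resamples of the test rows. The comparison grid evaluates
the full factorial 3 models × 5 top-k values {1, 5, 10, 15, 20} × 3 tissues
× 3 sequence sets, sharing one subject-level split; a shape-only baseline is
available by restricting candidates to the non-texture family.

## Scaled study sizes

The recovery experiments run by the tests and the reproduction script use
cohorts of 40 + 12 subjects on 48 × 48 × 24 grids with a reduced
3 × 2 × 2 × 2 texture grid, B = 200 and 200-tree forests; the full 240-point
grid is exercised on single volumes and small cohorts where only the
pipeline-structure counts are at stake. These sizes are the package's
defaults for desk-scale experimentation; the full-size 200 + 42 cohort and
complete grid are reachable through configuration alone. At smaller volumes
(≈32³) the MTL holds too few effectively independent voxels for the weak
N−2/N−3 effects (0.5 and 0.25 noise-SD units) to be detectable by any
estimator, which is why 48 × 48 × 24 is the floor for the recovery studies.

## Known limitations

* The univariate scorer inside the 0.632+ ranking does not refit a model per
  replicate; features interacting only multivariately are invisible to it.
* Negative-scan pooling puts three correlated rows per negative subject into
  each model; the subject-level split keeps them on one side, but the
  effective negative sample size is smaller than the row count.
* The orientation flip biases null 0.632+ scores above 0.5 by roughly
  E|AUC − 0.5|, which shrinks with cohort size.
* The HMRF segmenter is a stand-in for full probabilistic/partial-volume
  tissue segmentation; it produces hard two-class labels only.
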