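# Methods

This note records the statistical model, the synthetic-data generator, the
numerical choices, and the problem sizes the package adopts for its test and
acceptance suites.

## Experimental design model

The design is a category-decoding experiment on source code: 72 stimuli in a
two-level hierarchy — 4 functional categories of 18 stimuli, subdivided into
11 algorithm subcategories (ten of size 6, one of size 12; the size-12 class
shares its category with exactly one size-6 class). Each stimulus is shown 3
times across 6 runs of 36 task trials, at most once per run, with category
counts exactly balanced within run (9 per category). A trial is 16 s: 2 s
fixation, 10 s code display, 4 s response. Each run carries one leading 16 s
dummy trial, so a run lasts (36 + 1) × 16 = 592 s and a subject contributes
216 task trials.

`design.make_schedule` satisfies the constraints by per-run rejection
sampling: runs are filled sequentially per category, stimuli that must appear
in all remaining runs are placed first, and the attempt is restarted (up to
1000 times) if a quota cannot be met. The schedule is a deterministic
function of the seed.

## First-level GLM (beta series)

Each run is fit independently by ordinary least squares with one regressor
per trial — the "least-squares-all" beta-series approach — giving one
coefficient volume per trial (216 per subject). Per-trial regressors are
10 s boxcars over the code-display phase only, convolved with a canonical
double-gamma HRF (gamma-pdf shapes 6 and 16, undershoot ratio 1/6, unit peak,
peaking near 5 s). Nuisance terms: six motion regressors, a discrete-cosine
high-pass basis with cutoff 128 s (K = floor(2·N·TR/cutoff) columns; K = 9
at 288 volumes, TR 2 s), and a constant — 52 columns for a 36-trial run. The
dummy volumes at the start of each run are discarded and onsets shifted
accordingly. Rank-deficient designs raise an error naming the collinear
columns (QR diagonal test) rather than silently pseudo-inverting.

The solver is `numpy.linalg.lstsq` on the in-mask voxels. With noise-free
data whose nuisance terms lie in the design span, betas are recovered to
~1e-15 relative error; the generator's cosine drift is deliberately *not* a
DCT basis column (half-sample phase offset), so drift is only approximately
absorbed — an intended realism limit.

## Searchlight decoding

Sphere membership uses the strict inequality ||d||² < r² in voxel units: 251
voxels at the default radius 4, 27 at radius 2 (a closed ball at radius 4
would add the 6 lattice points at exactly distance 4, giving 257). Spheres
truncated by the mask or grid edge keep whatever voxels remain.

Per sphere, decoding is leave-one-run-out (LORO) cross-validation with a
linear-kernel SVM (one-vs-one multiclass). In each outer fold the training
rows are z-scored per voxel (parameters from the training rows only,
zero-variance voxels mapped to 0) and clipped to [−3, +3]; the SVM cost is
chosen by an inner LORO grid search over {0.1, 1, 10} on the training runs,
ties going to the smallest cost; test rows are scaled with the training
parameters. Accuracy is pooled correct/total over folds.

Chance under class imbalance is the frequency-proportional guessing rate
Σpᵢ²: 0.25 for the 4×18 categories, 504/5184 ≈ 9.72 % for the subcategories.
Subcategory decoding additionally applies per-class misclassification cost
weights ∝ 1/frequency, normalized to mean 1.

## Group inference

Subject accuracy maps are smoothed with a 6 mm FWHM Gaussian
(σ = FWHM/2.3548/voxel size per axis; NaNs outside the mask treated as 0,
result restricted to the mask). Two one-sided random-effects tests follow:

* accuracy > chance: voxel-wise one-sample t, voxel-level FWE by
  max-statistic permutation with per-subject sign flips of (map − chance);
* accuracy–behavior correlation: voxel-wise Pearson r against a behavioral
  covariate, cluster-extent FWE by score-permutation null of the maximum
  cluster size, cluster-forming threshold p = 0.001 one-sided (the t cutoff
  mapped to r via r = t/√(df + t²)), 18-connectivity components.

Permutation FWE was chosen over random-field theory because it is exact
under exchangeability and testable at small grid sizes; the test suite
checks the realized familywise false-positive rates on pure noise. The
conjunction is the voxel-wise AND of the two significance masks, reported as
a fraction of all searchlight centers. The scalar statistic t = r√(n−2)/√(1−r²)
reproduces reported values: r = 0.789, n = 30 → 6.795 (≈6.81 from unrounded
r); r = 0.698 → 5.158.

## Synthetic cohort generator

The generator produces data in which the analysis' target dissociation is
true by construction:

* **Geometry**: a superellipsoid mask (exponent 4, a rounded box) inscribed
  in the grid — 5864 voxels at the default 20×24×20, 2 mm grid. The rounded
  box, rather than an ellipsoid, leaves corner room for regions at small
  grids.
* **Regions** (cubes, scaled to the grid): `frontal_like`
  (category-informative, expertise-coupled), `temporal_like` (category- and
  subcategory-informative, expertise-coupled), `visual_like`
  (category-informative, fixed gain), `null` (no information). The coupled
  pair sits at one end of the longest axis, the uncoupled pair at the other,
  so searchlight/smoothing spillover from coupled regions cannot reach the
  regions that must stay out of the correlation-significance mask.
* **Patterns**: one zero-mean pattern per (region, class), normalized to
  unit per-voxel RMS so that a region's gain equals its per-voxel signal
  amplitude independent of region size. Class information lives in the
  multivoxel pattern, not the regional mean. Each subject sees the base
  pattern plus a zero-mean perturbation of 20 % of its norm.
* **Gains**: coupled regions 0.05 + 0.45 × expertise; visual-like fixed 0.4;
  trial volumes add the gain-scaled class pattern plus unit-variance Gaussian
  noise (beta-series path) or are HRF-convolved into BOLD with drift, motion
  nuisance and noise (GLM path).
* **Subjects**: three expertise groups with means 0.45/0.70/0.95 (SD 0.08,
  clipped to [0, 1]); an affine rating scale for reporting. Behavior follows
  a linear psychometric map from chance to a task ceiling (1.0 category, 0.8
  subcategory) with a 2 % lapse rate; unanswered trials count as incorrect.
  At n = 30 this calibration lands near the reported group means (~75 %
  category, ~64 % subcategory) and gives a strong expertise–behavior
  correlation.

Realism limits, by intent: no spatial autocorrelation in the noise, no
physiological confounds, box-shaped regions, and a drift term only
approximately spanned by the high-pass basis. The generator supports the
package's claims about the *analysis* (recovery, error control,
reproducibility), not about brains.

## Problem sizes and numerical choices

Decoding cost is dominated by the per-sphere SVM fits (~21 ms per center at
216 trials × 6 folds, single cost). The package therefore separates scales:

* **Default pipeline scale** (`PipelineConfig` defaults): 30 subjects,
  20×24×20 grid, radius 4, full cost grid — hours of CPU; intended for real
  use via the CLI.
* **Desk scale** (tests, acceptance report): 12 subjects (4/4/4), 12×16×12
  grid (1176 mask voxels), radius 2, single cost 0.1, 500 permutations —
  about 6 minutes, exercising the identical code path. At this scale the
  recovery run shows accuracy significance covering all informative regions,
  correlation significance covering exactly the coupled pair, and a
  conjunction Dice against the searchlight-dilated coupled truth well above
  0.3.
* **Error control**: 50 pure-noise cohorts on a 10×12×10 grid with 500
  permutations; realized voxel- and cluster-level familywise false-positive
  rates must stay within α + 2·binomial SE of α = 0.05.

Reproducibility: every stage draws its seed from one master seed through a
SHA-256-derived substream (`pipeline.stage_seed`), so reruns with the same
config are bit-identical; subject order never enters any statistic except
through floating-point summation order (tested to 1e-10).
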