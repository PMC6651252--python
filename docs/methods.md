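# Methods

## Pipeline model and assumptions

The pipeline assumes a single fruit on a pale, slightly bluish
background, imaged top-down in 8-bit sRGB. Its core premise is
chromatic: peel pixels — green through yellow — have R > B, background
pixels have R ≤ B, and brown senescence spots have R ≈ B. The
red–blue map `I_RB = R − B` therefore carries the segmentation signal;
values are clipped to [0, 255] rather than shifted, which collapses the
whole background to 0 and sharpens the bimodality Otsu's criterion
relies on. Otsu ties are broken toward the lowest threshold and the
foreground is `I_RB > t`. Morphological cleanup follows the classical
order: opening with a disk of radius 10 px (removes speckle), hole
filling by border flood fill (repairs the enclosed holes left by brown
spots), then retention of the largest 8-connected component (one fruit
per scene). Throughout, x indexes rows from the top and y indexes
columns from the left, 0-based.

ROI placement draws `a ~ U{15..35}`, `α ~ U(0.1, 0.2)`,
`β ~ U(0.15, 0.25)` from a per-image seeded generator. The horizontal
offsets multiply the fruit's span `y_ref′ − y_ref`; a "literal" variant
multiplying the *sum* `y_ref′ + y_ref` is kept behind
`roi_variant="literal"` for comparison, but it walks off the frame
whenever the fruit is right of center, which is why the span form is
the default. The tip ROI's row origin `x_roi − 48` is applied verbatim
and clamped to the frame; note that it necessarily places `48 − a`
rows of the tip patch above the fruit's top row, so the tip patch can
never lie more than `a/48` (≤ 73%) on the fruit — on-mask coverage is
checked per ROI and reported as a warning (or an error in strict mode)
rather than silently resampled.

## Descriptor conventions

Several encoding details are under-determined by any standard and are
fixed as follows. Grayscale is ITU-R BT.601 luma rounded to the
nearest integer, for both LBP and HOG. LBP neighbors are ordered
clockwise from the top-left corner, bit k−1 weighted 2^(k−1), with
ties (neighbor = center) counting as 1; the 1-px patch border is
skipped, giving 46 × 46 codes per ROI. The 58 uniform codes (≤ 2
circular transitions) occupy bins 0–57 in ascending code order and all
others share bin 58; each 59-bin histogram is L1-normalized so the
three ROI blocks are comparable. Hue components (HSV H and L\*ch h)
are averaged arithmetically: banana peel hues live in roughly 40–100°,
far from the 0/360 wrap, so a circular mean would change nothing but
the code's simplicity. HOG uses Prewitt kernels with replicate-padded
borders; orientation is `atan2(Gy, Gx)` folded into [0, π) — so an
intensity step across rows lands in the bin containing π/2 — with hard
(nearest-bin) magnitude votes into 9 equal bins `[kπ/9, (k+1)π/9)`,
and per-block L1 normalization guarded by ε = 1e-12 (an all-flat block
stays all-zero).

## Classifier choices

Naive Bayes uses univariate Gaussian class-conditionals — the
descriptors are continuous — with variances floored at 1e-9 times the
largest overall feature variance. LDA solves the generalized
symmetric eigenproblem for S_b against S_w with a ridge of
1e-6 · trace(S_w)/d, keeps at most c − 1 = 3 directions ordered by
eigenvalue with a first-nonzero-positive sign convention, and
classifies by nearest projected centroid (ties to the lowest label).
When d ≥ m the features are first projected onto the leading principal
components reaching 90% cumulative variance, capped at m − c
components — the standard small-sample repair, which activates for the
972-dim shape descriptor at m = 200 and stays off for color and
texture. The SVM solves each one-against-one dual by
maximal-violating-pair SMO to a KKT gap of 1e-3 with box constraints
[0, C], C = 1 by default (the comparison is across descriptors, not a
C sweep); the bias is minus the midpoint of the final violating pair,
and multiclass ties are broken by the largest summed |decision value|,
then the lowest label. Features are z-scored with training statistics
before LDA and SVM (scatter matrices and the QP are scale-sensitive
across the 18/177/972-dim descriptors); naive Bayes sees raw features,
being per-feature scale-equivariant. All fits are deterministic given
the input ordering.

Cross-validation is stratified (class-balanced folds), re-partitioned
per repeat from seeds derived by counter offset from one master seed;
the reported statistic is the macro-averaged recall pooled over each
repeat's folds, summarized as mean ± sample standard deviation over
the repeats (not over the 200 individual folds). Printed recall and
accuracy percentages round half-up to one decimal.

## What the synthetic scenes emulate — and what they do not

The generator renders a crescent-shaped fruit (a thick band around a
parabolic centerline whose tips curve upward) so the ROI formulas are
exercised on realistic bounds, on a gray cloth with a +12 blue bias.
Stage appearance defaults are design choices, not measured values:

* **Base hue** descends monotonically with ripeness and the stage
  ranges are disjoint — MS1 75–100°, MS2 56–64°, MS3 48–55°, MS4
  42–47° — giving the stage-separated color structure the pipeline
  assumes. Green hues stay below ~105° because at 120° R equals B and
  the chromatic premise would break.
* **MS2 green patches** (≈ 28% of peel area) are soft-edged ellipses:
  real part-green peel blends gradually, so patch outlines read as
  color, not as spot-like texture edges.
* **MS4 brown spots** (Poisson mean 25, radius 3–7 px) have a flat
  R ≈ B core and a sharp radial falloff over the outer half-radius:
  the core punches enclosed holes in the raw chromatic mask (the
  failure mode the morphology stage repairs) and the falloff spreads
  strong gradients over most of the spot area (the texture/shape
  signature of senescence spots). Spots are confined to the central
  half of the peel face with matching end margins — on a curved fruit,
  spots near the silhouette are foreshortened to near-invisibility —
  which also keeps spot holes enclosed rather than biting into the
  outline.
* **Peel micro-texture** is modeled as longitudinal ridge striations (a
  random-phase sinusoid following the curved centerline, added equally
  to all channels so the chromatic map is untouched) whose amplitude
  and wavelength grow with ripeness (2.5 px→25 gray levels, 4→10 px),
  plus a faint isotropic mottle (4 gray levels). Without
  stage-dependent micro-texture, LBP and HOG would carry no
  information at all about MS1–MS3, which contradicts how informative
  texture is on real peel; a periodic pattern keeps histograms nearly
  phase-invariant, so within-stage texture variance stays realistic
  and low.
* **Noise and illumination**: i.i.d. per-channel Gaussian noise
  (σ = 3, clipped to [0, 255]) and a linear brightness ramp (±4%)
  across the image — the simplest structures that stress Otsu and the
  color means.
* Occasional small dark defects (Poisson mean 0.5 per scene, any
  stage) emulate transport damage.

Scenes are pure functions of (config, appearance, seed); dataset
elements get seeds by counter offset so any single scene is
regenerable in isolation.

What passing tests on these scenes shows: the pipeline's stages
compose correctly, the descriptors respond to the appearance cues they
are designed for, and the classifiers recover well-separated stages at
the study's sample sizes. What it does not show: performance on real
photographs — real peels have 3-D shading, specularities, shadows,
non-elliptical patch shapes and camera artifacts none of which are
modeled, and the synthetic appearance parameters were never calibrated
against measured banana statistics (none are published for this
dataset). The headline accuracies on synthetic scenes are therefore a
functional check, not a claim about field performance.

## Numerical details and edge cases

Otsu requires at least two occupied gray levels and errors on constant
maps ("no foreground"). An empty mask after opening, a single-pixel
region, or a fruit narrower than three ROI widths raise typed errors.
The SMO solver errors with the residual KKT gap if the iteration cap
(200 000) is reached; duplicate fits are bit-identical because working
pairs are chosen by deterministic argmin/argmax. LDA's ridge keeps
S_w positive-definite even with collinear features; PCA components are
additionally capped at the data rank. Degenerate HOG blocks (zero
gradient energy) normalize to zero rather than NaN. Model files are
`.npz` archives with a versioned JSON metadata entry; feature CSVs
carry a schema-version comment line.

## Problem sizes

The default experiment uses 200 training and 120 test scenes
(50/30 per stage) at 240 × 320 px — chosen to mirror the study's
sample sizes while keeping a full run under a minute on one CPU. The
20×-repeated 10-fold cross-validation protocol is available
(`run_cv=true`, `crossval` subcommand) but off by default in
`run-experiment` since it multiplies training cost by 200.
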