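# Methods

This note documents the models and procedures the package implements, the
parameter choices that matter, and the places where a convention had to be
fixed by design.

## Co-occurrence matrix

`compute_glcm(img, d, θ)` counts gray-level transitions at displacement
`(d, θ)` with offsets 0°→(0,+d), 45°→(−d,+d), 90°→(−d,0), 135°→(−d,−d).
Accumulation is **symmetric**: each pixel pair increments both `(i,j)` and
`(j,i)`, so every matrix is symmetric and its total equals twice the number
of in-bounds pairs. Symmetry is the convention the Haralick statistics
assume, and it makes the quadrant subwindow layout meaningful (the two
off-diagonal quadrants are transposes of each other). The number of gray
levels is fixed at 256 for every descriptor path — subwindow coordinates
are defined on a 256×256 matrix — and higher-bit or RGB inputs are first
collapsed (luminance weights 0.299/0.587/0.114) and linearly rescaled.

Subwindows are inclusive at both corners: `(0,0)–(127,127)` spans 128 bins.
The four standard subwindows are the 128×128 quadrants; the SHAPE
descriptor uses its own set of 12 windows ranging from 64×64 to 192×192.

## Multi-scale stack

Scales are the original image plus Gaussian-smoothed versions with kernel
sizes k = 3 and k = 5, σ = 1. The kernel is the discrete sampled Gaussian
normalized to unit sum; borders are handled by edge replication (a zero
border would inject spurious dark-level transitions into the GLCM); the
filtered image is rounded back to integer levels, since the co-occurrence
matrix is a histogram over discrete levels.

## Haralick statistics

The matrix is normalized to a joint probability table; the 13 statistics
use the marginal, sum (`i+j`) and difference (`|i−j|`) distributions, with
logarithms in base 2 and `0·log 0 := 0`. Two definitions in the classical
literature are ambiguous and are fixed here as constants of the package:
*sum variance* is the variance of the sum distribution about the **sum
average** (the variant that is dimensionally consistent), and *difference
variance* is the variance of the difference distribution about the
difference average. Degenerate matrices (zero marginal variance, e.g. a
constant image) return correlation = 0 and IMC1 = 0 with a warning instead
of aborting, so subwindow pipelines stay total; an entirely empty window
contributes an all-zero 13-block with a warning.

## Run-length features on the matrix

The co-occurrence matrix is itself treated as an image. Raw bin counts are
heavy-tailed, so they are log-compressed:
`c → floor(n · log(1+c)/log(1+max c))` with n = 16 levels (configurable,
`rl_levels`). Runs are maximal constant segments along rows (0°), columns
(90°), and both diagonal families (45°, 135°, including length-1 corner
diagonals). The 11 indicators follow the classical formulas; because levels
are indexed from 0, the gray-level emphasis families weight by `(i+1)` so
level 0 does not divide by zero. Note that on a symmetric matrix the 0° and
90° run matrices coincide; the directions are retained for fixed descriptor
layout and for use on asymmetric windows.

## Level-curve SHAPE features

Slices are taken at heights 1–19 step 2 on the **raw counts** (strictly
`counts > h`); the matrix is deliberately not normalized, because the
low-height region is stable while the peak region fluctuates with image
noise. Blobs are 8-connected; the main blob is the largest by pixel count
(ties broken by smallest row-major pixel). The moment-equivalent ellipse is
computed from the covariance of blob pixel coordinates: axis lengths are
4·√eigenvalue and the orientation is the major-axis eigenvector angle,
measured from the row axis, in [−π/2, π/2).

The nine evolution features are a fixed, documented set: (1–2) slope and
intercept of least-squares area vs. height, (3–4) mean and slope of
eccentricity vs. height, (5) circular mean orientation (angle-doubled,
since orientation is an axis), (6) total centroid path length across
consecutive non-empty levels, (7) number of non-empty levels, (8) mean blob
count per level, and (9) the area ratio of the highest to the lowest
non-empty level (in (0,1] by level-set nesting). They capture the evolution
of the level curves with height; they are this package's own concrete
instantiation of that idea, chosen to be deterministic and dimension-9, and
results obtained with them are not comparable feature-for-feature with
other shape-evolution codebases.

## Curvature histograms

Levels 1–13 step 3 (five levels). At each main-blob contour pixel (a blob
pixel with a 4-neighbor outside the blob) and for each disc radius
r ∈ {3, 5, 7}, the curvature estimate is the weighted fraction of disc
pixels belonging to the blob — 0.5 on a straight edge, below 0.5 on convex
boundary, above on concave. Contour pixels themselves carry weight ½: the
discrete contour is a width-1 stand-in for the continuous boundary curve
that splits the disc, and half-weighting removes the bias that otherwise
pushes the straight-edge estimate to ≈0.62 at r = 3. With this convention
the calibration fixtures give 0.500 on an edge and 0.254 at a right-angle
corner. Estimates per (level, radius) are quantized into 8 equal-width bins
on [0,1] and normalized to unit sum (all-zero for empty levels). Radii and
bin count are configurable (`cu_radii`, `cu_bins`); the defaults suit the
256×256 matrix scale.

## PCA subspace descriptor

Each (d, θ) matrix is flattened row-major and normalized to probabilities
(so source image size does not dominate the variance — a documented choice,
not a universal convention), then projected onto the principal subspace
with the smallest component count reaching 99% cumulative explained
variance. One model per (d, θ) slot (and per window/scale in the sub/sca
ensembles), always fitted on the training fold only; projections are
concatenated. Zero-variance training data yields a single-component model
with all-zero projections and a warning. A memory guard in the CLI refuses
runs whose flattened training matrices exceed a configurable budget
(default 2 GiB).

## Classifiers, fusion, evaluation

Each panel trains an SVM pipeline (feature standardization + SVC). Kernel
and hyperparameters are selected by inner stratified 5-fold CV on the
training partition, by accuracy, over: linear and RBF with
C ∈ {0.01, 0.1, 1, 10, 100}, RBF γ ∈ {2⁻⁵…2³}, polynomial degrees {2, 3}.
Per-class decision scores (one-vs-rest) are z-normalized per column —
population standard deviation, constant columns to zero — and fused by
weighted sum. Within-method weights: whole matrix 4 / subwindows 1
(SHAPE: first five windows 1, remaining eight 0.5); multi-scale: original
image 4 / smoothed 1, uniformly over windows. Cross-method fusion
re-normalizes each method's fused panel before the weighted sum. Outer
evaluation is stratified 5-fold CV with a fixed seed; the reported value is
the mean over folds of the one-vs-all AUC averaged over classes (ties count
0.5). Nothing fitted — scorer, scaler, PCA model, score normalizer — ever
sees test-fold labels.

## Synthetic data

The test-bench generator produces constant, stripe, checkerboard, blob-field
and correlated-noise textures. The correlated field is a separable AR(1)
process (IIR filtering of white noise along rows then columns), standardized,
clipped at ±3σ and quantized to 256 levels; its lag-1 autocorrelation ρ is
the single knob, and the GLCM diagonal concentration grows with it, so the
Haralick correlation statistic orders ρ correctly — this gives sharp oracle
tests. The canonical benchmark is 50 images per class, 64×64, ρ = 0.2 vs
0.8: well-separated but realistic sizes for a texture CV experiment, small
enough that a full 5-fold run of HR/HRsub completes in about a minute.
`make_gaussian_bump_matrix` builds a matrix-shaped Gaussian bump whose
level-set ellipses are known in closed form (semi-axes
√(2·log(A/h)·eigvals Σ)), the oracle used for ellipse-recovery tests.

What the synthetic data does *not* emulate: real co-occurrence structure of
biological textures is neither separable nor stationary, class differences
are rarely captured by a single correlation parameter, and realistic class
overlap is absent. Passing the benchmark therefore demonstrates that the
pipeline is correct and leak-free and that the descriptors respond to
spatial correlation as designed — not that any particular AUC would be
attained on real medical datasets.

## Numerical choices and degenerate inputs

Entropies use `0·log₂0 := 0`, no epsilons. Images smaller than 2×2, or
displacements with no valid pairs, are rejected. Empty level slices,
all-zero matrices and empty subwindows propagate as flagged zero vectors
where a pipeline must stay total, and as errors where a statistic is
genuinely undefined (all-zero matrix into `haralick_13`, empty run matrix
into `rl_indicators`). All descriptor paths are deterministic; the only
randomness is in the synthetic generators and CV splits, both seeded.

## Problem sizes

Oracle checks run on 50 random images up to 32×32 (co-occurrence), 50
random 8×8 matrices (Haralick), and 50 images across four run directions
(run length); ellipse recovery uses 20 random anisotropic bumps across ten
heights; the classification benchmark uses 100 images of 64×64. These sizes
make the full suite and the acceptance script each complete in about a
minute on one CPU while exercising every code path at full descriptor
dimensionality.

## Known limitations

* The nine SHAPE evolution features and the curvature radii/bin defaults
  are package-defined conventions (see above); AUCs are not
  feature-compatible with other implementations of the same ideas.
* Inner model selection uses accuracy, which can be a blunt criterion for
  heavily imbalanced data; the outer metric is AUC.
* `LD` on large sample counts is memory-hungry (n × 65536 doubles per
  (d, θ) slot); the CLI guard refuses rather than thrash.
* Run-length features on 0° and 90° duplicate information on symmetric
  whole-matrix windows (see above).
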