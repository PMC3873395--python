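# cooctex

Texture descriptors extracted from the gray-level co-occurrence matrix
(GLCM), with multi-scale and subwindow extraction schemes and SVM
score-fusion ensembles, for grayscale texture image classification —
the setting where these methods matter most is biological and medical
imaging (cell phenotypes, histopathology, virus micrographs), but nothing
here is specific to a modality.

## The descriptors

All methods start from the co-occurrence matrix `C(d, θ)`: a 256×256
histogram counting, for every pixel pair at displacement distance `d ∈ {1, 3}`
and orientation `θ ∈ {0°, 45°, 90°, 135°}`, the pair of gray levels
observed. Accumulation is symmetric (each pair counted in both orders).
Five descriptor families are extracted from it:

* **HR** — the 13 classical Haralick statistics of the normalized matrix
  (energy, correlation, inertia, entropy, inverse difference moment,
  sum/difference average, variance and entropy, and the two information
  measures of correlation), concatenated over the 8 `(d, θ)` matrices
  (13 × 2 × 4 = 104 features).
* **GR** — 11 gray-level run-length indicators (SRE, LRE, GLN, RLN, RP,
  LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE) computed on the co-occurrence
  matrix itself: bin counts are log-compressed to 16 levels, and maximal
  runs are enumerated along four directions `θ_GL` (11 × 2 × 4 × 4 = 352
  features).
* **SH** — the matrix viewed as a 3D surface is sliced at heights
  1, 3, …, 19; the largest 8-connected blob of each slice is fitted by its
  moment-equivalent ellipse, and nine features summarize how area,
  eccentricity, orientation and centroid evolve with height.
* **CU** — area-ratio curvature along the main blob's contour at heights
  1, 4, …, 13: a disc of radius `r ∈ {3, 5, 7}` is centered at each contour
  pixel and the blob-area fraction inside (≈0.5 on straight edges, ≈0.25 at
  corners) is quantized into 8-bin histograms.
* **LD** — the flattened, probability-normalized matrix projected by PCA
  onto the subspace retaining ≥ 99% of training variance.

Each descriptor has three extraction schemes: the whole matrix (`HR`),
whole + subwindows of the matrix (`HRsub`: the four 128×128 quadrants,
SVM weights 4:1:1:1:1; `SHsub` uses 13 windows with weights 1 for the first
five, 0.5 for the rest), and additionally over a Gaussian multi-scale stack
(`HRsca`: kernels k = 3 and 5, σ = 1, giving 15 panels with weight 4 for
original-image panels and 1 for smoothed ones). Every panel trains its own
SVM (kernel and hyperparameters chosen by inner 5-fold CV); per-class
decision scores are z-normalized (mean 0, std 1) and combined by weighted
sum rule. Cross-descriptor ensembles: `SUM2` = HRsca + GRsca, `WS2` = 2:1,
`W2`/`W3` = SUM2:SHsca at 2:1/3:1. Performance is one-vs-all AUC averaged
over classes under stratified 5-fold cross-validation, with per-fold
retraining of scorers, normalizers and PCA models.

## Worked example

```python
import cooctex as ct

# two AR(1) texture classes differing in spatial correlation
ds = ct.two_class_ar1_dataset(n_per_class=10, size=(32, 32), seed=3)

s = ct.glcm_set(ds.images[0])          # the 8 (d, theta) matrices
v = ct.haralick_13(s[(1, 0)])          # 13 statistics of the d=1, 0° matrix
for name, val in zip(ct.STAT_NAMES[:5], v[:5]):
    print(f"{name:28s} {val:.4f}")

hr = ct.run_experiment(list(ds.images), ds.labels, "HR", ct.CvPlan(5, seed=3))
print("HR  5-fold one-vs-all AUC:", round(hr["auc_mean"], 3))
```

prints

```
energy                       0.0006
correlation                  0.2344
inertia                      2755.6764
entropy                      10.8274
inverse_difference_moment    0.0233
HR  5-fold one-vs-all AUC: 1.0
```

The low-correlation class (ρ = 0.2) yields a Haralick correlation near 0.23
at unit lag, while the ρ = 0.8 class concentrates mass near the matrix
diagonal; the two are perfectly separated by the Haralick descriptor under
5-fold cross-validation (AUC 1.0).

The same workflows are available from the shell:

```
cooctex synth --out data --n-per-class 50 --size 64 --rho 0.2,0.8 --seed 1
cooctex glcm data/img_00000.png --d 1,3 --theta all --out glcms
cooctex extract --manifest data/manifest.csv --method HRsub --out features
cooctex evaluate --manifest data/manifest.csv --method HRsub --seed 1 --out results
```

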