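# Methods

This note records the model, the conventions the implementation commits to,
the choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish.

## Difficulty scoring

A case's difficulty is the fraction of readers who false-positived on it:
ratings are on the 1–5 RANZCR scale, a rating ≥ 3 on a truth-normal case is
an error, and a reader contributing several ratings to one case (multiple
suspected findings) is collapsed to their highest rating first. Tertile
labels sort by score descending with ascending case id as a deterministic
tie-break; the outer tertiles have exactly `floor(n/3)` cases each and the
remainder is intermediate. With ties across the tertile boundary other
conventions produce slightly different splits; this one is symmetric and
reproducible. BI-RADS densities A/B map to the low-density group, C/D to
high.

## Preprocessing

Masks are `pixels > threshold` with the canonical threshold 100 on the
8-bit scale, auto-scaled by `2^(bit_depth-8)` for deeper images; only the
largest 8-connected component is kept, which removes detached corner labels
and markers while retaining the pectoral muscle (deliberately — false
positives cluster near it). When nothing exceeds the threshold the library
refuses and asks for an explicit per-image override rather than guessing.
Right-sided views are flipped left-right so the chest wall is always on the
left; image and mask are cropped to the tight half-open bounding box
`[r0, r1) × [c0, c1)` of the mask. Orientation is an involution on
right-sided pixels and cropping is idempotent.

## Regions

The lattice anchors distinct (non-overlapping) `block_size`² blocks at the
crop origin; tiles extending past the image are discarded (no padding), and
a tile is retained iff ≥ `coverage_min` (default 0.9) of its pixels are
breast. The coverage knob is the explicit answer to the open question of
how boundary-straddling blocks are treated: near-full blocks keep block
statistics comparable and avoid background contamination. The inscribed
square is the exact maximal all-true square, found by monotone bisection on
the side length with an integral-image window test; ties go to the smallest
row, then column.

## Features

All 34 features are registry-driven (`gistgrf/data/grf_registry.csv`): 30
GLCM Haralick statistics, 2 NGTDM coarseness values, 2 first-order ranges,
each as a lattice (`ROI_Std_`, population standard deviation across blocks)
or inscribed-square (`SQ_`) variant. Conventions the implementation fixes:

* **Quantization**: 64 equal-width levels over the region's own min–max,
  for GLCM and NGTDM alike. This makes every texture feature invariant to
  constant intensity shifts and indifferent to bit depth; 64 levels balance
  resolution against co-occurrence sparsity in 214²-pixel blocks.
* **GLCM**: symmetric accumulation at the four standard directions (0°,
  45°, 90°, 135°) with Chebyshev stride `d` (offsets `(0,d), (-d,d), (-d,0),
  (-d,-d)`, the convention of the classic co-occurrence literature and of
  MATLAB's `graycomatrix`); each direction normalised then averaged. Lattice
  features use distance 3, inscribed-square features distance 9, and the
  lattice `Sum_of_squares_variance` uses distance 9 per the registry.
* **Haralick definitions**: entropies in log base 2 with `0·log 0 = 0`;
  correlation defined as 0 when a marginal is degenerate; sum variance about
  the sum average and difference variance as the variance of the
  `p_{x−y}` distribution (the modern convention); information measures from
  HXY/HXY1/HXY2 with IMC2's radicand clamped at 0.
* **NGTDM coarseness**: square neighbourhoods (3×3 lattice, 9×9 square
  variant), neighbourhood mean excluding the centre, only pixels whose full
  window lies inside the region; `1/(1e-9 + Σ p_i s_i)`, hence capped at
  1e9 for uniform regions.
* **Range**: max − min of raw, unquantized gray values.
* **Degenerate lattices**: fewer than two retained blocks leaves the
  across-block standard deviation undefined; all lattice features are set
  to 0 with a logged warning rather than failing the image.

Normalisation is a column-wise z-score with parameters estimated on a
designated fit set; constant columns map to 0. The default analysis fits
fold-internally inside the cross-validation (no leakage); `paper_mode`
fits once on all rows before model building, matching the original
global-normalisation workflow.

## Models and validation

Per-view classifiers are stagewise additive ensembles of depth-limited
regression trees under logistic loss (the LogitBoost / adaptive logistic
regression family), realised with scikit-learn gradient boosting: 500 trees
by default, learning rate 0.1, at most 10 splits per tree (11 leaves),
seeded and deterministic. Each image is one training instance carrying its
case label, so a view model sees the left and right image of every case;
the alternative of averaging the two sides is available but stacking
doubles the training data and matches the median aggregation idiom.

Validation is leave-one-out at the case level: every image of the held-out
case is excluded from training, normalisation parameters are re-fit on the
fold's training rows, and the case score is the median of its image scores.
The fused CC+MLO score is by default the median of the pooled per-image
scores of both view models (four values); the alternative median of the two
case-level scores degenerates to their mean and is available as
`case-median`. Predictor importance is the summed weighted impurity
decrease per feature across all split nodes divided by the number of trees,
so the importances exactly conserve total split gain; top-k selection
breaks ties by registry order, and the scree mode cuts after the largest
drop at position ≥ 2 of the sorted profile — an explicit elbow heuristic
standing in for a visual scree reading.

## Statistics

AUC is the Mann–Whitney pair statistic with ties at 0.5. Confidence
intervals and model comparisons use DeLong's structural-component
(co)variance with a two-sided normal test; identical score vectors return
z = 0, p = 1 by convention. The implementation reproduces R `pROC`'s
`roc.test`/`ci.auc` to 1e-9 on fixed examples (frozen in the test suite)
and its type-I error is nominal (within [0.03, 0.07] at α = 0.05 over 2000
null replicates). At n = 10 its normal-approximation p agrees with the
exact within-case permutation distribution only in the clear-effect regime;
for moderate effects at that sample size the two genuinely differ (up to
~0.3), which is a property of the approximation, not an implementation
artifact. Kruskal–Wallis tests (scipy, tie-corrected) drive the per-feature
difficult-vs-easy table — case-averaged by default, since the four views of
a case are not independent observations — and the density-group comparison
of difficulty scores. Headline per-feature p-values are unadjusted, with a
Benjamini–Hochberg column alongside.

## Synthetic cohorts

The generator emulates exactly the statistical structure the pipeline
assumes: four views per case; a breast-shaped half-ellipse (semi-axes
0.42·h and 0.78·w, jittered ±10% per image) attached to the chest-wall side
on a dark background (base 140 and 5 on the 8-bit scale — thresholding at
100 is guaranteed to work); a triangular pectoral wedge (+30) on MLO views;
an optional detached 20×20 corner label block at 220; and parenchymal
texture as Gaussian noise (σ = 10) low-pass filtered at a correlation
length of 4 px. Difficult cases scale the noise variance and correlation
length by `1 + effect_size` in all four views (the class is a case-level
property). Reader panels false-positive with configurable probabilities
(defaults 0.6 difficult / 0.1 easy, 130 readers); 5% of reader-cases get a
duplicate independent rating to exercise the collapse rule. Densities
follow a 10/40/40/10 A–D mix, assigned independently of difficulty.

What passing tests show: the pipeline recovers a planted global texture
difference (leave-one-out fused AUC ≥ 0.8 at effect size 1.0 with 60
cases), behaves at chance on null cohorts, and keeps its statistical tests
calibrated. What they do not show: anything about real mammographic
difficulty — the planted noise-variance effect is a stand-in, not a claim
about what makes a real normal case hard to read, and the geometry is
schematic (no vendor characteristics, no pixel-spacing variation, no real
parenchymal patterns, density labels carry no pixel correlate).

## Problem sizes

Full-scale runs use 214-pixel blocks, matching full-resolution mammograms
(thousands of pixels per side). The bundled simulations run at reduced
scale — 256×256 images with 64-pixel blocks, 60-case cohorts, 50-tree
ensembles — chosen so the lattice still tiles the synthetic breast with
several blocks and the whole recovery study completes in minutes; the
planted effect is comfortably detectable at this scale. The block size
scales with image size as a ratio, not as an absolute.

## Known limitations

* Null leave-one-out AUC on 40-case analyses has high seed-to-seed variance
  (sd ≈ 0.14); it is unbiased (checked over 20 seeds on pure-noise feature
  matrices) but single-seed values far from 0.5 are unremarkable.
* The tertile split cannot reproduce an arbitrary external split under tied
  scores (the tie rule of the original reader study is unknown).
* The exact GLCM direction set, quantization depth and the lattice-range
  convention (`ROI_Std_Range_all` = std of per-block ranges here) are
  implementation commitments where the literature varies; all are
  configurable and recorded in run provenance.
* DICOM support is generic single-frame grayscale (MONOCHROME1 inverted on
  load); no vendor-specific handling.
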