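# Methods

This note records the modelling choices behind `stubbletex`: the exact
definitions the descriptors implement, the conventions chosen where the
classical definitions are ambiguous, what the synthetic generator does and
does not emulate, and the numerical and problem-size choices.

## Texture descriptors

### Co-occurrence (GLCM)

For a patch with `k` gray levels, offset distance `d` and direction θ, the
matrix counts **ordered** pixel pairs: entry (i, j) is the number of pixels
of value i whose partner at the offset has value j. The angle→offset
convention, in (row, col) steps with the row axis growing downward, is
0° → (0, +d), 45° → (−d, +d), 90° → (−d, 0), 135° → (−d, −d) — i.e. 0°
reads each row left to right. Pairs are *not* symmetrized by default
(the worked example of the small 8-level toy image counts (1, 2) twice
without also counting (2, 1)); a `symmetric` flag adds the transpose for
users who want the Haralick-standard symmetric matrix.

Statistics are always computed on the probability-normalized matrix:
normalization keeps `asm` and `hom` in (0, 1] and makes values comparable
across patch sizes. Entropy uses log base 2 with `0·log 0 := 0`.
Correlation uses the marginal means and standard deviations of the
normalized matrix; for a single-gray patch both marginal deviations vanish
and the ratio is 0/0, so `cor` is **defined as 0** there — a fixed sentinel
keeps the feature finite and testable. Because only index differences and
standardized moments enter the six statistics, the choice of 0-based gray
indices does not affect any of them.

The default 256 gray levels on a 200-pixel patch make the matrix extremely
sparse (≤ ~200 nonzero entries out of 65 536); the implementation sums
over nonzero entries only, and a `requantize(levels)` utility (uniform
binning) is available when coarser matrices are wanted.

### Run lengths (GLRLM)

Q(i, j) counts maximal runs of gray i with length exactly j along the scan
lines of one direction; every pixel belongs to exactly one maximal run, so
ΣΣ j·Q(i, j) equals the pixel count for all four directions (the diagonal
directions partition the patch into its diagonals). Gray bins are 1-based
in the statistics (gray value g carries weight i = g + 1), so the 1/i²
weights of the low-gray emphases are defined for the darkest bin.

Two of the classical printed formulas are dimensionally inconsistent and
were repaired to the standard forms: the run percentage is
`rr = S / (pixels scanned)` (the widely used "run percentage"; the
textbook-circulated variant ΣΣ S/(j·Q(i,j)) divides by zero entries), and
the long-run low-gray emphasis is `lrlg = ΣΣ j²·Q/(S·i²)` (the variant
without the divisor is not a normalized emphasis). A third repair was made
on the same grounds: the long-run high-gray emphasis is
`lrhg = ΣΣ i²·j²·Q/S`; the commonly reprinted form is identical to the
plain high-gray emphasis `hgr = ΣΣ i²·Q/S`, which drops the run-length
weighting the statistic's name requires and would duplicate an existing
feature. With these forms, `sr ∈ (0, 1]` and `lr ≥ 1` whenever any run
exists.

### Rotation-invariant LBP

P = 8 neighbours at radius R = 1; the sum over neighbours runs i = 0..7
(eight terms — an inclusive upper bound would double-count one neighbour).
For R = 1 the circle's sample points coincide with the 3×3 neighbourhood,
and the diagonal neighbours are taken at the integer corners without
interpolation — this keeps the oracle (explicit bit-rotation enumeration)
exact and differs from implementations that bilinearly interpolate the
diagonal samples. The threshold is `s(x) = 1` iff `x ≥ 0`, so a flat
neighbourhood maps to the all-ones word (ri code 255). Borders are
edge-replicated so the code image keeps the full 10×20 geometry and the
2×4 grid of 5×5 sub-regions tiles it exactly. Histograms use the 36
attainable rotation-invariant codes for P = 8, enumerated once and fixed
in ascending order, rather than 256 mostly-empty bins.

## Wavelet fusion

Single-level separable 2-D DWT with **symmetric (half-sample) padding**.
The padding rule matters: a 10×20 patch is shorter than the long filters
(coif5 has 30 taps), so boundary handling materially changes the
coefficients; the choice is recorded in every `SubbandSet` for
reproducibility, and perfect reconstruction holds for all 22 bases under
this mode. Sub-band naming follows the LL/LH/HL/HH ↔ A/H/V/D
correspondence, with V = HL the *vertical detail*: intensity changes across
columns — exactly where vertical stalk striation lands.

GLCM needs integer gray levels, and the classical pipeline leaves the
coefficient→gray mapping unspecified; here each selected sub-band is
min–max rescaled per patch to [0, 255] with round-half-up, a constant
sub-band mapping to all zeros. Per-patch min–max discards the absolute
coefficient scale (only the sub-band's *structure* survives), which keeps
the sub-band GLCM on the same gray scale as the original image's.

Screening evaluates all four sub-bands of every base by tenfold-CV
accuracy of the sub-band GLCM features under the configured classifier
(BPNN by default), returning pairs above the 0.7 accuracy threshold in
descending order. The default fusion configuration is (coif3, V).

## Classifiers and evaluation

The classical pipeline names the three families but none of their
hyper-parameters; the defaults here are the smallest standard designs,
all overridable per `ModelSpec`:

* RF: 100 trees;
* BPNN: one hidden layer of 32 logistic units, at most 500 epochs, seeded
  (`MLPClassifier`; the optimizer may stop at the epoch cap without
  formal convergence — accepted, since the evaluation is cross-validated);
* SVM: C = 1, polynomial degree 3, `gamma = 1/(n_features·var)`.

Features are z-scored with training-fold statistics only, so no
information leaks into held-out folds. CV is stratified tenfold with
seeded shuffling; the confusion matrix (rows true, columns predicted,
fixed order soil_leaves/stubble/film) is accumulated over held-out folds,
and Se/Sp treat stubble vs the pooled rest. The 8:2 train/test split
utility is stratified per class (`round(0.2·n)` test samples each) —
class balance is assumed by the pooled-negative metric definitions.

## Detection

The ROI scanner tiles with stride = block size by default (non-overlapping;
configurable for denser scans) and enumerates blocks top-to-bottom,
left-to-right, classifying each independently; all three labels are kept
internally, and only stubble blocks are framed (1-px red outline) in the
annotated copy. ROI placement is a configuration parameter — where the
stubble row sits in the frame is scene-specific.

## Synthetic data

The generator's defaults are the study conditions: 10×20 patches, 256
gray levels, 350 patches per class (1050 total) by default, three
separability levels. Class models:

* stubble: vertical square-wave stripes, period 4 px, levels 60/190
  (≈ the contrast of sunlit stalks against shadowed ground), per-stalk
  brightness jitter (σ = 6);
* soil_leaves: white speckle around level 110, σ = 35, lightly smoothed
  (grain correlation length under a pixel);
* film: near-constant level 225 with faint large-scale undulation.

Separability sets the additive sensor noise: σ = 2 (easy), 14 (medium),
26 (hard); *hard* additionally tilts the striation by 12° (oblique
driving tips the stalks) and blurs with σ = 0.8 px (camera shake). Fields
composite the same textures into 480×640 frames as vertical column bands
with a block-level truth mask; stripe phase is a function of absolute
column, so any block cut inside a stubble band contains striation.

What the generator does **not** emulate: perspective foreshortening,
shadows and illumination gradients, mixed-content blocks at band
boundaries (the mask labels blocks by their centre column), film
specularity, and partially buried stubble. Passing benchmarks on this
data therefore demonstrates that the pipeline wiring and descriptors are
correct and that the class signals they target are recoverable — not that
the same accuracies transfer to field imagery, where class overlap is far
larger.

## Problem sizes and numerical tolerances

* Oracle-equivalence checks: 100 seeded random patches per angle and
  configuration; brute-force enumerators live in the test suite and share
  no code with the implementation. Statistics agree with direct-summation
  oracles to 1e−10.
* Wavelet round trip: max |error| < 1e−8 across all 22 bases.
* Benchmark: 150 patches/class for CV accuracy and the field scan
  (held-out field from a different seed); screening runs the full 22×4
  grid at 15 patches/class — the smallest size stratified tenfold CV
  admits, chosen to keep the 880 classifier fits to a few minutes.
* The permutation-null test allows ±0.15 around chance (binomial noise at
  n = 180 plus classifier variance); the RF out-of-bag vs CV comparison
  allows 5 points (two estimators of the same error).

## Known limitations

* GLRLM scan lines at 45°/135° read whole diagonals; run statistics are
  direction-dependent but invariant to reading order within a line.
* The directed (non-symmetric) GLCM makes 0° and 45°/135° features differ
  from symmetric-matrix implementations (e.g. scikit-image with
  `symmetric=True`); the 0°-direction statistics agree with scikit-image's
  directed mode, which the tests cross-check.
* The BPNN epoch cap means per-fold models are early-stopped rather than
  converged; accuracies are stable under the fixed seeds but individual
  weight vectors are not meaningful.
* On easy/medium synthetic data the benchmark saturates (Ac = 1.0), so the
  fusion feature's gain is bounded below by zero rather than strictly
  positive; the hard level exists to probe the degraded regime.
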