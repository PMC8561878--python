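# stubbletex

Texture-feature toolkit for detecting cotton stubble rows in post-harvest
field imagery.

## The problem

After cotton harvest in mulched fields, residual plastic film must be
recovered; machines that pull film-recovery tools follow the rows of short
upright stalk remnants ("stubble") left by the stalk whipper. A vision
system guiding that operation has to tell three kinds of surface texture
apart in small image patches:

* **stubble** — upright stalks photographed as high-contrast vertical
  striation (the positive class),
* **soil_leaves** — soil and shredded leaves between rows: isotropic,
  grainy speckle,
* **film** — residual plastic mulch: bright, smooth, low-variance sheets.

`stubbletex` implements the full classical pipeline for this task: three
hand-computed texture descriptors, a wavelet sub-band fusion feature,
classical classifiers with tenfold cross-validated evaluation, and a
block-scanning detector that localizes stubble inside a region of
interest. Because no public labeled patch set exists for this scene, a
seeded synthetic generator emulates the three texture classes and full
field frames with ground truth, so every stage is testable end to end.

## Method

The classification unit is a 10×20-pixel 8-bit grayscale patch. From it
the toolkit computes:

* **GLCM** (gray-level co-occurrence matrix): for offset distance d = 1 and
  each direction θ ∈ {0°, 45°, 90°, 135°}, the matrix G(i, j) counts
  ordered gray pairs (i, j) at that offset. Six statistics are taken on
  the probability-normalized matrix — angular second moment
  `asm = ΣΣ G(i,j)²`, entropy `ent = −ΣΣ G log₂ G`, correlation
  `cor = (ΣΣ ij·G − uᵢuⱼ)/(sᵢsⱼ)`, dissimilarity `dis = ΣΣ G|i−j|`,
  contrast `con = ΣΣ G(i−j)²`, homogeneity `hom = ΣΣ G/(1+(i−j)²)` —
  giving a 4 × 6 = **24-dimensional** feature.
* **GLRLM** (gray-level run-length matrix): Q(i, j) counts maximal runs of
  gray level i with length exactly j along each direction's scan lines;
  eleven run statistics (short/long-run emphasis, gray-level and
  run-length non-uniformity, run percentage, low/high-gray and joint
  emphases) give a 11 × 4 = **44-dimensional** feature.
* **Rotation-invariant LBP**: each pixel's 8 neighbours at radius 1 are
  thresholded at the centre (`s(x) = 1` iff `x ≥ 0`), packed into an 8-bit
  word `LBP₈,₁ = Σᵢ₌₀⁷ s(gᵢ−g_c)2ⁱ`, and reduced to
  `min{ROR(LBP₈,₁, i)}` over the 8 cyclic rotations (36 attainable
  codes). The code image is split into eight 5×5 sub-regions whose
  36-bin histograms concatenate to a **288-dimensional** feature.
* **Wavelet fusion**: one level of 2-D DWT splits the patch into the four
  sub-bands A/H/V/D (LL/LH/HL/HH). A selected sub-band — by default the
  vertical detail of `coif3`, where upright-stalk striation concentrates —
  is min–max quantized back to 256 gray levels and its 24 GLCM statistics
  are appended to the original patch's, giving the **48-dimensional**
  fusion feature. The base/sub-band choice is made by *screening*: all
  22 candidate bases (db1–db10, sym2–sym8, coif1–coif5) × 4 sub-bands are
  scored by tenfold-CV accuracy of their sub-band GLCM features, keeping
  pairs above a 70 % accuracy threshold.

Classifiers are random forest, a single-hidden-layer back-propagation
network (BPNN), and SVMs with linear/polynomial/RBF/sigmoid kernels.
Evaluation accumulates a 3-class confusion matrix over held-out folds of
a stratified tenfold CV and reports accuracy
`Ac = (TP+TN)/(TP+TN+FP+FN)`, sensitivity `Se = TP/(TP+FN)` and
specificity `Sp = TN/(TN+FP)` with stubble positive and the other two
classes pooled as negative. Detection tiles a 100×200 ROI into 10×20
blocks, classifies each block, and frames stubble blocks in red.

## Worked example

```python
import numpy as np
from stubbletex import (SynthConfig, generate_dataset, ModelSpec,
                        evaluate_cv, fusion_feature)
from stubbletex.texture import glcm_feature_vector

ds = generate_dataset(SynthConfig(separability="medium", n_per_class=150, seed=11))
X = np.array([glcm_feature_vector(p).values for p in ds.patches])
rep = evaluate_cv(X, ds.labels, ModelSpec("BPNN", seed=11), folds=10, seed=11)
print(f"GLCM+BPNN  Ac={rep.Ac:.3f} Se={rep.Se:.3f} Sp={rep.Sp:.3f}")

Xf = np.array([fusion_feature(p).values for p in ds.patches])
repf = evaluate_cv(Xf, ds.labels, ModelSpec("BPNN", seed=11), folds=10, seed=11)
print(f"fusion+BPNN Ac={repf.Ac:.3f} (feature dim {Xf.shape[1]})")
```

prints

```
GLCM+BPNN  Ac=1.000 Se=1.000 Sp=1.000
fusion+BPNN Ac=1.000 (feature dim 48)
```

On the medium-noise synthetic benchmark the three classes are fully
separable by co-occurrence statistics — the per-fold confusion matrices
in `rep.per_fold` show where residual errors would land on harder data
(at `separability="hard"`, tilted and blurred striation, accuracies drop
below 1 and the fusion feature's advantage becomes visible).

The same pipeline is scriptable from the shell:

```sh
stubbletex synth --out data --n-per-class 150 --separability medium --seed 11 --field
stubbletex eval --manifest data/manifest.csv --features glcm --models BPNN --out report.csv
stubbletex screen --manifest data/manifest.csv --threshold 0.7 --out screen.csv
stubbletex train --manifest data/manifest.csv --feature fusion --model BPNN --out model.joblib
stubbletex detect --model model.joblib --image data/field.png --roi 150,220,100,200 \
    --out-csv detections.csv --out-image annotated.png
```

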