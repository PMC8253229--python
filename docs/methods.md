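# Methods

## The measurement model

A plot image is an 8-bit sRGB raster with a boolean inclusion mask.
Index means are taken over included pixels only; the mask exists because
rows cropped obliquely out of an aerial orthomosaic carry black padding
("hallow") that would otherwise dilute every index — the package's
recommended path is to rotate the mosaic axis-parallel first and crop
with an explicit pixel grid, with `mask_dark_fill` (default threshold 0,
pure black only) as a fallback for residual fill. Rotation uses
nearest-neighbor resampling so no colors are invented that could move a
pixel across a hue-band boundary; padding pixels are black and excluded
from the mask. Multiples of 90° are exact array rotations.

### Color conversions

All conversions assume the standard sRGB transfer function and the D65
white point (2° observer) — the consumer-camera default. HSI is the
classical triple: intensity is the channel mean in [0, 1], saturation
`1 − min/mean`, hue the arccos-form chromaticity angle with red at 0°,
yellow at 60°, green at 120°. Achromatic pixels (equal channels) have no
hue and never enter hue statistics; a round-off guard treats
saturation ≤ 1e-12 as achromatic. Lab and Luv come from scikit-image.
The per-plot hue is a circular (vector) mean over chromatic pixels,
since arithmetic means are wrong near the 0°/360° wrap.

### The vegetation fractions

GA and GGA are the fractions of included pixels whose **angular hue**
falls in [60°, 120°] and [80°, 120°] respectively. The hue wheel with
green at 120° is the natural home of these bands (60° = yellow is the
senescent end, 120° = green the healthy end); pure green sits exactly on
the 120° boundary, so the bands are closed intervals and a 1e-9 boundary
tolerance absorbs floating-point round-off. The CIE-Lab *hue angle*
`atan2(b*, a*)` is also provided as an operation, but it is not the
classification axis: on that scale yellow sits near 103° and green near
136°, so a 60–120° Lab band would exclude healthy green canopies
entirely and invert the sign of the GA–wilting relationship. CSI is
`100·(GA − GGA)/GA`; when GA = 0 the ratio is undefined and the package
reports 0 with a logged warning rather than propagating a non-numeric
value into regression (such plots are flagged for exclusion).

GA and GGA are reported as fractions in [0, 1] (not percent), matching
the scale on which the published per-image means are quoted; CSI uses
the ratio, so the scale cancels.

## The wilting models

The ordinal model is proportional-odds cumulative-logit, parameterized
exactly as the published formulas print it:
`logit P(Y ≤ j) = ε + α_j` with strictly increasing thresholds α and a
single linear predictor ε shared across boundaries. Category
probabilities follow by successive differencing with the last category
as the complement, which guarantees a probability vector that sums
to 1. The binary model is `P(turgid) = logistic(ε + intercept)`, with
the turgid/wilted split at score 2 (the irrigation trigger).

Four fitted models are stored as literal-constant presets. One caveat is
flagged rather than repaired: the aerial binary preset (`model4`) as
printed yields near-zero turgid probability at typical aerial index
values (its intercept of −31.74 is not offset by the magnitudes its
coefficients produce), which suggests a sign or labeling slip in the
original equation. It is implemented exactly as printed.

Model levels are part of the model: the proximal ordinal preset spans
0–3 only because scores 4–5 were absent from its training data, and
predictions never emit levels outside the model's range.

### Fitting and selection

New models are fitted by maximum likelihood (statsmodels `OrderedModel`
and `Logit` under the hood; parameters are converted to the
parameterization above, which flips the sign of the slope vector
relative to statsmodels' threshold-minus-xβ convention). No
regularization is applied; estimates diverging past 1e4 in magnitude or
failing to converge raise a fit error, so complete separation is
surfaced, not silently shrunk.

Stepwise selection is the classical p-value procedure: forward entry and
backward elimination by likelihood-ratio χ²(1) tests, both at 0.05 by
default (the conventional entry/stay levels). A rank check on the
candidate design skips predictors collinear with those already included,
so duplicated columns can never both enter. The selected model is
reported alongside the null model (no predictors; its log-likelihood has
the closed form of the empirical category frequencies) and the full
model, each with AIC = −2ℓ + 2k and SC = −2ℓ + k·ln n.

### Classification rules

The top-probability score is the estimate; ties break toward the lower
(healthier) score, a deterministic and conservative choice for
irrigation triggering. Three correctness rules are scored: exact match
(`first`), match to either of the two highest-probability scores
(`second_probability`), and match within ±1 score (`nearest_score`,
boundary scores using only their existing neighbors). The contingency
matrix always tallies (visual, top) counts, so it is identical across
rules; only the correctness tally differs. Second-probability accuracy
requires full probability vectors and is refused on count matrices,
where the runner-up is unrecoverable. Percentages are reported rounded
to whole numbers but stored at full precision.

One arithmetic discrepancy in the shipped reference matrices is
documented rather than forced: the 2018 proximal ordinal matrix
recomputes to 100% under the nearest-score rule (every misclassified
plot is in an adjacent score), while the printed summary row says 99%.
The 2019 matrix recomputes to 95.8% → 96%, as printed.

### Concordance and cross-validation

The c-statistic is computed by pair enumeration: over all observation
pairs with different truth labels, the fraction in which the
higher-truth observation has the higher score, ties counting half. For
binary truth this equals trapezoidal ROC AUC (cross-checked against
scikit-learn in the tests). For ordinal truth a scalar score is needed;
the package uses the probability-weighted expected level, a choice
isolated behind one function.

k-fold CV partitions the rows with a seeded generator (`n mod k` folds
get one extra row); leave-one-out pools the n held-out scores into a
single c-statistic and is fully deterministic. CV refits reuse the
predictor set selected on the full data — selection is not re-run per
fold — which matches a validate-the-trained-model design but carries a
known optimistic bias. Folds (or left-out points) whose refit hits
separation are excluded from the mean and logged.

## The synthetic generators

Two tiers, deliberately decoupled:

- **Pixel tier.** Elliptical leaf blobs accumulate over bright sandy
  soil (RGB 170/140/110) until a target cover fraction is reached.
  Cover falls from 0.95 (score 0) to 0.28 (score 5) and the leaf HSI hue
  center from 115° to 62°, with per-plot jitter (cover SD 0.06, hue SD
  6°) reflecting the large plot-to-plot variation real fields show
  within one visual score; wilted leaves are also slightly lighter
  (channel-mean intensity 0.26 → 0.36). Soil is brighter than foliage in
  both channel-mean intensity and CIE lightness, as midday bare soil is,
  which is what gives both indices their positive correlation with
  wilting. Leaf colors are drawn in HSI (wilting is natively a hue
  shift) and converted to sRGB through the exact inverse of the arccos
  hue formula.

- **Table tier.** Index vectors are drawn from plausible ranges (GA/GGA
  via a beta construction that enforces GGA ≤ GA; CSI computed, never
  drawn) and ordinal scores are sampled from a *known* cumulative-logit
  generating model, giving exact generative truth for parameter-recovery
  and selection tests. Measurement noise is added after score sampling,
  clipped to each index's legal range, and CSI recomputed.

Default field size is 168 plots with all six score levels present, the
scale of the study field the package emulates. All generators are pure
functions of (config, seed).

**What the synthetic data does not show.** The renderer has no shadows,
specular highlights, soil-moisture darkening, plant architecture, or
camera noise, and its index–wilting signal is considerably cleaner than
real canopies: fitted models on rendered fields reach concordance near
1.0 (and occasionally hit complete separation, which the pipeline
surfaces as excluded CV folds), versus 0.82–0.93 reported for field
data. Passing tests therefore demonstrate correctness of the pipeline's
arithmetic and directional behavior (e.g. all 11 correlation signs), not
field-level accuracy.

## Problem sizes

The test suite renders fields of 168 and 200 plots at 64×64 px per plot,
simulates index tables of up to 5000 rows, and runs 10-fold and
leave-one-out CV on ~120-row tables; the full suite completes in well
under a minute. These sizes give stable sign patterns and ~3-SE recovery
margins while keeping iteration fast.

## Known limitations

- JPEG color profiles are ignored; all input is assumed plain sRGB.
- The near-black threshold for residual compression artifacts at plot
  edges defaults to 0 (pure black only) and may need raising for real
  JPEG crops.
- The `hue` index column is HSI hue; whether the original extraction
  software reported HSI or Lab hue for its "hue" column is ambiguous in
  the source material, and HSI is the documented choice here.
- Ordinal AUC depends on the expected-score scalarization; other
  scalarizations (e.g. top score) would give slightly different values.
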