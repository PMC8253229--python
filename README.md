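# canopywilt

Estimation of peanut (*Arachis hypogaea* L.) leaf wilting from RGB imagery.

Leaf wilting is the visible symptom of low soil-moisture stress in peanut
and is traditionally scored by eye on a 0–5 scale (0 = fully turgid,
5 = near-dead; scores of 2 or more are treated as "wilted" and mark the
proposed irrigation trigger). Visual rating of hundreds of breeding plots
is slow and subjective. This package implements the image-based
alternative: plot photographs — proximal shots or rows cropped from an
aerial orthomosaic — are reduced to eleven color-space indices, and
logistic models turn those indices into wilting scores.

## What it computes

**Indices** (per plot, over non-masked pixels): HSI intensity, hue and
saturation; CIE-Lab L\*, a\*, b\*; CIE-Luv u\*, v\*; and three vegetation
fractions on the angular hue wheel (red 0°, yellow 60°, green 120°):

- GA (green area) — fraction of pixels with hue in [60°, 120°],
- GGA (greener area) — fraction in [80°, 120°] (always ≤ GA),
- CSI (crop senescence index) — `100·(GA − GGA)/GA`.

**Models.** Ordinal wilting scores use the proportional-odds
cumulative-logit form written directly as published,

```
logit P(Y ≤ j) = ε + α_j,   α_0 < α_1 < …,
```

with ε a linear predictor over the indices; the binary turgid/wilted
model is `P(turgid) = logistic(ε + intercept)`. Four published fitted
models ship as presets (`model1`/`model2` ordinal proximal/aerial,
`model3`/`model4` binary proximal/aerial). New models are fitted by
maximum likelihood with stepwise predictor selection and AIC/SC
reporting.

**Evaluation.** Accuracy matrices with three correctness rules (exact
top-probability match; second-probability; nearest-score ±1), the
concordance c-statistic / ROC AUC, index–wilting Pearson correlations,
and 10-fold plus leave-one-out cross-validation.

**Synthetic data.** A canopy renderer (leaf cover and leaf hue degrade
with the wilting score over bright sandy soil) and a direct index-table
simulator with a known generating model make the full pipeline testable
without field imagery.

## Worked example

```python
import numpy as np
import canopywilt as cw

# render a wilted (score 4) plot and extract its indices
plot, stats = cw.render_canopy(4, seed=8)
vec = cw.extract_indices(plot)
print(round(vec.ga, 3), round(vec.gga, 3), round(vec.csi, 1))
# 0.22 0.0 100.0   <- little green canopy left, none of it deep green

# score it with the published aerial ordinal model
pred = cw.predict_ordinal(cw.get_model("model2"), vec)
print(pred.top_score, pred.second_score)
# 5 4
```

Only 22% of this plot's pixels sit in the yellow-to-green hue band and
none in the stricter green band, so the senescence index is at its
100-point maximum — a yellowing, sparse canopy that the aerial model
ranks as severely wilted (top score 5, runner-up 4).

The `analysis/` scripts run the same pipeline at field scale: simulate a
168-plot field, extract indices, check that all 11 index–wilting
correlation signs match the published directions, fit and cross-validate
both model families, and recompute the published accuracy tables. The
`canopywilt` console command exposes each stage
(`simulate`, `extract-indices`, `fit`, `predict`, `evaluate`, `cv`).

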