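# enmecotype

Ecological-niche-model-based delineation of livestock ecotypes.

Village livestock populations — scavenging chickens in particular — are
shaped by the habitats they forage in, yet are usually managed as one
undifferentiated "indigenous" group. This package implements the full
protocol for turning environmental raster layers and village GPS points
into *candidate ecotypes*: populations whose habitats are environmentally
distinct enough to expect distinct local adaptation.

The pipeline, stage by stage:

1. **Raster stack** — single-band GeoTIFF / ESRI ASCII grid layers
   (climatic, soil, vegetation/land-cover groups) aligned onto one WGS84
   grid with a shared validity mask.
2. **Occurrences** — each surveyed village (one GPS point) is expanded to
   the centre plus nine uniform points in a 1.2 km² square, ten points per
   village; districts are the modelling unit (20–30 points each).
3. **Variable screening** — Shapiro–Wilk annotation, Spearman rank
   correlations (|r_s| ≥ 0.6 treated as strong), PCA inspection, then an
   iterative selection that alternates dropping low-contribution variables
   (< 5%) and the weaker member of each correlated pair until stable,
   keeping the minimum-AICc stable set across beta multipliers.
4. **Maximum-entropy niche model** — the Gibbs distribution over background
   cells `raw(x) = exp(λ·f(x))/Z` minimising

   ```
   −mean_presence[λ·f(x)] + log Σ_background exp(λ·f(x)) + Σ_j β_j |λ_j|
   ```

   with feature classes L/Q/P/H/T/C and per-feature bounds
   `β_j = BM · c_class(m) · s_j/√m`. Fitting is cyclic coordinate descent
   with proximal-Newton soft-threshold steps and a monotone line search;
   raw, logistic (`raw·e^H/(1+raw·e^H)`) and cumulative (0–100) outputs
   are rank-consistent.
5. **Parameter selection** — AICc over a feature-class × beta-multiplier
   grid (the default grid has 16 fc-sets × BM 1..12 = 192 candidates),
   with K counted as non-zero coefficients; 75/25 train/test split plus
   regionalised (longitude-blocked) ten-fold cross-validation.
6. **Evaluation** — rank-based AUC, jackknife with-only/without gains,
   percent contribution credited along the training path, permutation
   importance, response curves.
7. **Ecotype delineation** — pairwise Pearson correlation of logistic maps
   and Hellinger niche overlap `I = 1 − ½Σ(√p−√q)²` (plus Schoener's D),
   Euclidean distances between similarity-matrix rows, agglomerative
   clustering under four linkages, linkage chosen by the largest
   agglomerative coefficient, tree cut into k ecotypes, per-ecotype maps
   combined by cell-wise maximum.

A synthetic-landscape generator (`enmecotype.synth`) builds correlated
Gaussian-random-field stacks with planted ecotype suitability surfaces and
a village sampling design, so the whole protocol runs and is testable
without any data download.

## Worked example

The numbered scripts under `analysis/` run the protocol on the packaged
synthetic scenario (64×64 grid, 3 planted climatic drivers, 2 correlated
distractors, 2 noise decoys, 1 categorical layer; 4 ecotypes × 4 districts
× 2 villages):

```sh
python analysis/01_simulate_landscape.py
python analysis/02_screen_variables.py
python analysis/03_tune_parameters.py
python analysis/04_fit_and_evaluate.py
python analysis/05_delineate_ecotypes.py
```

prints (seed 1):

```
selected variables: temp_max, temp_wet, precip_wet
chosen: feature classes H, beta multiplier 1.0
pooled model: AUC train 0.901, test 0.868, CV mean 0.846
district models: n=16, training AUC 0.985-0.999
overlap_I: AC single=0.77, complete=0.80, average=0.79, ward=0.89; chose ward, k=4, ARI vs planted truth = 1.00
pearson_r: AC single=0.73, complete=0.78, average=0.76, ward=0.88; chose ward, k=4, ARI vs planted truth = 1.00
```

Read: the screening recovered exactly the three planted driver layers; the
hinge feature class at beta multiplier 1 won the AICc grid; each district's
habitat is modelled almost perfectly (AUC ≥ 0.985) while the pooled model
is deliberately broader; Ward linkage structures both similarity matrices
best, and cutting its tree at k = 4 reassembles the four planted ecotypes
perfectly (adjusted Rand index 1) under both metrics.

The same protocol is scriptable via the CLI (`enm-ecotype run --seed 1
--out run/`, or stage-by-stage with `simulate | screen | tune | fit |
evaluate | compare | cluster`), driven by a YAML config.

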