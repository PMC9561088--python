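# Methods

## The model

The niche model is a presence-background maximum-entropy (Gibbs) model.
Given feature vectors `f(x)` at every background cell `x` of the study
grid and at `m` presence points, the fitted distribution is
`raw(x) = exp(λ·f(x) − log Z)` with `Z = Σ_background exp(λ·f(x))`, where
`λ` minimises the convex objective

```
f(λ) = −mean_presence[λ·f] + log Σ_background exp(λ·f) + Σ_j β_j |λ_j|.
```

This is the maximum-entropy distribution subject to the presence feature
expectations, relaxed by per-feature L1 bounds
`β_j = BM · c_class(m) · s_j / √m`: `s_j` is the presence-sample standard
deviation of feature j (floored at 1e-3 so every coefficient stays weakly
penalised), `c_class(m)` the published per-class default constant
interpolated piecewise-linearly in m (linear/quadratic/product:
1.0→0.2→0.05 at m = 10/30/100; categorical 0.65→0.25 at 0/17; threshold
2→1 at 0/100; hinge 0.5), and BM the user-facing beta multiplier.

**Features.** Continuous covariates are min-max scaled over the background
and expanded into linear, quadratic, pairwise-product, threshold
(indicator above a knot) and hinge (forward/reverse ramps) features; knots
sit at evenly spaced interior quantiles of the background distribution
(library default 30 per variable), which bounds the basis size
independently of the data. Categorical layers always get one indicator
per level. At projection time, values outside the training bounds are
clamped to the scaled unit interval and the clamp count reported.

**Optimiser.** Cyclic coordinate descent: each coordinate takes a
proximal-Newton step (soft-thresholding at `β_j/h_j`, with `h_j` the
background feature variance under the current model) followed by a halving
line search on the exact objective, so the objective is non-increasing at
every accepted update; convergence when a full sweep improves the
objective by less than 1e-7 (at most 500 sweeps). A screening shortcut
skips coordinates already satisfying their KKT condition. Every accepted
update's gain increase is recorded with its feature index — this training
path is what percent contribution is computed from (product features split
their credit evenly between variables). The unit tests audit the KKT
conditions and compare the fitted objective against an independent
general-purpose convex optimiser on small instances.

**Outputs.** `raw` sums to one over the projection grid's valid cells;
`logistic = raw·e^H/(1+raw·e^H)` with H the entropy of the fitted
distribution over the training background (so a cell of average
log-suitability scores 0.5); `cumulative(x) = 100·Σ_{raw(y)≤raw(x)} raw(y)`.
All three are rank-consistent cell-wise. Backgrounds are shared across
district models (all valid cells of the common mask, presences excluded
from the background rows), which makes per-district maps directly
comparable — the prerequisite for the pairwise-similarity stage.

## Selection stages

**Screening.** Associations are always Spearman rank correlations with
midrank ties (the covariates are generally non-normal; a Shapiro–Wilk
table documents this but nothing downstream depends on it). Correlation
pruning keeps a variable iff |r_s| < 0.6 against everything already kept,
visiting candidates in (priority rank, name) order — deterministic and
order-invariant. The iterative selection fits the model on the current
set, drops variables contributing < 5%, then resolves remaining correlated
pairs (|r_s| ≥ 0.6 over background cells — the model's domain, not the
presence sample) in favour of the higher-contribution member, repeating
until stable; one stable set is scored per beta multiplier and the
minimum-AICc set wins.

**AICc grid.** Candidates are fc-set × BM pairs in stable order; the
default grid is the 15 non-empty subsets of {L, Q, H, T} plus
{L, Q, P, H, T}, each at BM 1..12 (192 candidates). K counts non-zero
coefficients; the log-likelihood is the presence log of `raw` normalised
over the full grid; candidates with n − K − 1 ≤ 0 are flagged invalid and
never selected. Ties break by smaller K, then smaller BM, then grid order.

**Splits.** The test set holds round(0.25·n) randomly drawn points; the
training remainder is sorted by longitude and cut into ten contiguous
blocks — a deliberately spatial ("regionalised") cross-validation
structure. All splits are seeded.

## Similarity and clustering

Pearson correlation is computed on the logistic surfaces over jointly
valid cells; niche overlap I and Schoener's D on the raw surfaces, each
renormalised to sum one on the shared mask (so both are invariant to
positive rescaling, bounded in [0,1], equal one iff the distributions
coincide, and I ≥ D always). Pairs sharing fewer than 10 valid cells are
errors, not numbers.

Populations are clustered on Euclidean distances between the *rows* of a
similarity matrix — each population is described by its similarity profile
to all others — under single, complete, average and Ward linkage (Ward via
the standard Lance–Williams recurrence on a condensed Euclidean distance
matrix, heights on the distance scale, matching the agnes/ward.D2
convention). The agglomerative coefficient is AC = mean over objects of
(1 − first-merge height / final-merge height); the linkage with the
largest AC is kept, ties preferring ward > average > complete > single.
k is a config override (the packaged scenario pins k = 4, mirroring a
protocol where the final group count is set by combined inspection) or,
absent an override, the k maximising mean silhouette width on the input
distances. Ecotype maps combine members by cell-wise maximum of their
cumulative surfaces: a cell is suitable for an ecotype if suitable for any
member population.

## The synthetic landscape

The generator emulates the statistical shape of a real environmental
stack, not its geophysics. Continuous layers are smoothed Gaussian random
fields (default blur radius 3 cells) mixed through the Cholesky factor of
a target correlation matrix; a categorical layer quantile-bins one extra
field. The packaged scenario is a 64×64 grid (~1 km cells in WGS84
degrees) with three "climatic" driver layers, one soil and one
vegetation distractor correlated 0.7 with a driver, two pure-noise decoy
layers, and a four-level categorical layer. The decoys are generated with
a short correlation length (blur 0.5 cells): they emulate fine-grained
nuisance layers, and — unlike large smooth random fields, which can align
with the handful of sampled patches by chance and mimic signal — they are
genuinely uninformative at the design's effective sample size.

Four ecotypes are planted as products of Gaussian suitability factors on
the drivers (width 0.3 in standardised units), with optima at the four
sign combinations of the first two drivers (±1.2) and the third driver
aligned with the first (±0.9) — a layout whose pooled presence marginals
are strongly non-uniform per driver, i.e. identifiable by an additive
feature model. Because smoothed random fields rarely reach an arbitrary
corner of driver space jointly, each optimum is snapped to the nearest
realised cell's driver vector, guaranteeing every ecotype an actual
habitat while preserving ≥ 6 widths of pairwise separation. Villages
(16 districts × 2, one ecotype per 4 districts) are drawn with probability
proportional to their ecotype's true suitability, jittered within the
cell, and expanded to ten occurrence points exactly as survey villages
are. Altitudes come from a separate smooth field scaled to 500–3,000 m so
the sampling table carries realistic zone labels.

What passing on this landscape does *not* show: robustness to survey GPS
error, to spatially biased (road-side) sampling, to layers at mixed native
resolutions, or to niches that drift along gradients rather than forming
compact optima. Real-data behaviour on those axes is untested.

## Numerical and design choices

- Cell convention: half-open cells, origin at the upper-left corner;
  points map to cells by floor of the inverse affine transform.
  Continuous layers resample bilinearly, categorical always nearest.
- The run configuration for the packaged scenario uses a reduced tune grid
  (L+Q and H at BM 1, 2), beta multipliers {1, 2} in the selection stage,
  10 knots in the selection basis and 6 knots in the final models; the
  full 192-candidate grid and the 30-knot basis remain the library
  defaults. The coarser final basis regularises per-district models fit
  on ~15 points, whose hinge staircases would otherwise isolate
  razor-thin environmental slices and make same-ecotype maps
  incomparable; the richer selection basis lets drivers absorb gain that
  would otherwise leak to decoys.
- Cross-validation refits are run for the pooled model only; per-district
  CV would multiply fitting cost without informing the maps the
  clustering consumes.
- Per-district expansion seeds derive from blake2b(global seed, district
  label), so adding or removing a district never perturbs the others'
  points.
- The packaged survey transcription preserves printed agro-ecology labels
  verbatim even where they contradict the stated altitude thresholds
  (e.g. a 1,662 m village labelled lowland); `classify_altitude` is
  informational and the printed labels win when echoing the table. The
  variable registry disambiguates a duplicated printed label for the two
  water-vapour-pressure months.
- Determinism: every stochastic step takes an explicit seed; the run
  report and log contain no timestamps, so identical config + seed yields
  byte-identical outputs. The clustering stage always reads the
  serialized similarity CSVs, making stage-wise reruns bit-identical to
  monolithic runs.

## Limitations

- No reprojection: all layers must already share a geographic CRS;
  alignment is affine resampling only.
- The optimiser is exact but single-threaded and dense; stacks far beyond
  ~10⁵ background cells × ~10³ features would need sparse features or
  subsampled backgrounds.
- Percent contribution is path-dependent by definition; different but
  equally optimal training paths could credit correlated variables
  differently.
- k selection by silhouette is a pragmatic default; the protocol's final
  group count is ultimately a judgement call exposed as a config override.
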