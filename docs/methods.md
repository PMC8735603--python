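# Methods

`esmsdm` implements a presence–background distribution-modelling workflow
for very rare species — the Ensembles of Small Models (ESM) strategy —
together with the downstream community products it feeds: binary
distribution maps, stacked richness surfaces, and a local Lee's L
spatial-concordance analysis with per-pixel Monte Carlo significance.
This note describes the models, the choices made where the design was
genuinely open, and what the synthetic test-bed does and does not show.

## The modelling problem

Species with 5–29 occurrence records cannot support a conventional
multi-predictor distribution model: the predictor/occurrence ratio
invites overfitting. The ESM strategy replaces one large model with all
C(p, 2) *bivariate* models over a screened predictor set (p = 5 gives 10
candidates per learner family), scores each by cross-validated Somers'
D = 2·AUC − 1, discards candidates no better than random (D ≤ 0), and
averages the rest with weights proportional to D. Two learner families
are ensembled and then averaged with weights proportional to their own
cross-validated D:

- **Random forest** — `sklearn.ensemble.RandomForestClassifier`,
  500 trees by default, honoring per-row case weights; probability is
  the mean tree vote.
- **Maxent-style penalized logistic** — a presence–background logistic
  model on the linear, quadratic, and pairwise-product features of the
  two predictors (the low-order maximum-entropy feature classes),
  z-scored on the training rows. The L1 penalty strength is selected on
  a 5-point path (C from 1e−2 to 1e2) by internal stratified 3-fold CV
  scored by held-out deviance, the standard criterion for penalized
  likelihood paths.

Presences carry case weight 1 and each of the n_b shared background
points carries n_presences/n_b, so the class weight totals are equal.
One background sample (default 10,000 points, uniform over jointly
valid cells) serves all species in a run.

## Cross-validation and evaluation

Skill is estimated with **10 repeated random stratified 80/20 splits**
(not 10-fold partitioning): each class contributes ⌈20%⌉ of its rows to
validation, so a 5-occurrence species validates on exactly one presence
per split. A single set of splits per species drives every stage —
per-pair scoring, technique-level scoring, and the final evaluation —
and no stage ever trains on its own validation rows.

The final ensemble is evaluated on **pooled out-of-split predictions**,
with one refinement: the prediction attributed to split *s* uses
sub-model selection, sub-model weights, and cross-technique weights
recomputed from the *other* splits only (leave-one-split-out). Without
this, the evaluated ensemble is selected partly on the noise of the very
split it is scored on, inflating the AUC of weak species; the
refinement costs no extra model fits because per-split validation
predictions are cached.

A caveat worth stating: even honest CV does not drive a *selected*
ensemble of a truly null species to AUC 0.5. With 20 candidate pairs and
a few dozen realized presences, some predictor always correlates
spuriously with the realized presence pattern, and the retained subset
inherits that correlation (we measure ≈ 0.62 on null species). The
calibrated null quantity is the *unconditional* mean cross-validated AUC
over all candidate bivariate models, which is ≈ 0.5; the test suite
asserts exactly that for null species, and the selected-ensemble AUC for
signal species.

Reported metrics per species: AUC (rank-based, ties = 1/2; verified
against an all-pairs oracle), Somers' D, TSS, sensitivity and
specificity at the binarization threshold. Sensitivity is reported only
for species whose final ensemble is better than random (AUC > 0.5).

## Thresholding and maps

Continuous suitability maps are integers on [0, 1000] (rounded per-cell
weighted probabilities × 1000). The binarization threshold is the
maximum sensitivity-plus-specificity (max-SSS / TSS-optimum) cutoff,
scanned over the observed pooled scores; ties break toward the lowest
candidate, and presence is score ≥ threshold — both conventions are
fixed so binary maps are bit-reproducible. Richness surfaces are
cellwise sums of binary maps, overall and per guild (mosses, liverworts,
sphagna); a nodata cell in a single species map counts as absence by
default so local gaps in one predictor do not hole the community
surface.

## Predictor derivation and screening

Spectral indices follow their standard formulas — EVI2 =
2.5·(NIR−RED)/(NIR+2.4·RED+1); NDWI1 = (NIR−SWIR1)/(NIR+SWIR1); BSI in
normalized-difference form ((SWIR1+RED)−(NIR+BLUE)) /
((SWIR1+RED)+(NIR+BLUE)), adopted because the frequently-printed variant
with unbalanced parentheses is not a well-formed expression — plus the
HV/HH backscatter ratio and the annulus-neighborhood TPI (elevation
minus the mean over cells at 15–20 pixel center-to-center Euclidean
distance, inclusive; near edges the partial annulus is used, and a cell
whose annulus lies entirely outside the raster is nodata).
Standardization is the z-score with the **population** (n) standard
deviation; the convention is fixed for golden tests and is immaterial
downstream. Collinearity screening drops, for every predictor pair with
|Pearson r| > 0.7 over the background points, the lower-priority member;
priority is an explicit list (default puts NDWI1 ahead of BSI — moisture
sensitivity is the ecologically preferred signal for poikilohydric
vegetation) because the retained member of a correlated pair is a domain
decision, not an automatic rule.

## Lee's L spatial concordance

For two aligned surfaces x, y with centered values x̃, ỹ and spatial
weights W (row-standardized queen contiguity by default; rook and an
identity scheme are available and recorded in output metadata), the
local statistic is

    L_i = n · (Wx̃)_i (Wỹ)_i / sqrt(Σ_k x̃_k² · Σ_k ỹ_k²).

With identity weights the mean of L_i reduces exactly to the Pearson
correlation, a useful degenerate check. Masked cells are excluded from
means, sums, lags and row normalization. Surfaces are block-mean
aggregated before analysis (e.g. 30 m → 300 m with factor 10); partial
edge blocks use available cells and fully-masked blocks are nodata.

Significance is per-pixel Monte Carlo: y is permuted across valid cells
(x and W fixed — the conditional-on-x null; permuting one variable is
the standard conditional randomization for bivariate association), L is
recomputed (cheap: the x-lag and the denominator are permutation-
invariant), and the observed value is ranked among {observed + n_sims
simulated}, giving attainable quantiles 1/1000 … 1000/1000 at the
default 999 simulations. Quantile > 0.975 is a significant positive
association, < 0.025 negative. For display, L is centered on its mean
and divided by the maximum |centered value|, guaranteeing [−1, 1] even
when the extreme deviation is negative.

Under perfect concordance (y = x) not every cell is classed positive:
cells whose centered spatial lag crosses zero carry no signal, so the
positive fraction on smooth 30×30 fields is ≈ 0.4–0.5, not ≈ 1. Under
independence the positive rate calibrates near the nominal 0.025.

## Synthetic test-bed

The generator produces the statistical structure the analysis assumes,
not remote-sensing physics:

- **Landscape** — Gaussian random fields (white noise smoothed with a
  Gaussian kernel, σ = range/2, wrap-around boundaries), z-scored;
  correlated layers by mixing independent fields through the Cholesky
  factor of a target correlation matrix, which controls expected
  pairwise Pearson r exactly. Defaults: 5 standardized, weakly
  correlated predictors, 30 m cells.
- **Plot network** — 389 plots by default, uniform over cells without
  replacement. Real plot networks cluster along access routes; a
  clustering knob is deliberately *not* asserted against any fidelity
  claim.
- **Species** — presence probability is the inverse logit of
  b0 + b1·A + b2·B + b3·A·B over a chosen predictor pair; the exact
  occurrence count (5–29) is met by weighted sampling of plots without
  replacement with probability ∝ the true surface, a seeded, documented
  procedure that reproduces per-species prevalence exactly. The true
  probability surface is retained for recovery tests.

For recovery experiments the "strong-signal" species uses intercept −3
and slope 3.5. The intercept matters: a zero-intercept logistic species
on a standardized Gaussian predictor has a presence-background AUC
ceiling of 0.75 regardless of slope, because its suitable area covers
half the landscape (in the steep-slope limit the presence distribution
is a half-normal and P(half-normal > normal) = 3/4). A negative
intercept confines the species to a small suitable area — the defining
property of a rare specialist — and raises the attainable AUC well above
the 0.7 recovery target.

What passing tests show: the pipeline recovers planted niche signals,
calibrates to null inputs, and every kernel matches an independent
oracle. What they do not show: performance on real reflectance products
(cloud contamination, sensor noise, spatially clustered sampling,
imperfect detection are all absent from the generator).

## Problem sizes and numerical choices

Replicated experiments in the test suite and the acceptance script use
scaled-down sizes chosen to keep full runs convenient on a single CPU:
grids 30×30–100×100, 150–1000 background points, 10–100 trees for
replicated forest fits, 999 Monte Carlo permutations. Defaults in the
API remain at the field-standard values (10,000 background points, 500
trees, 999 simulations). Degenerate inputs are contracts, not crashes:
zero-variance layers, single-class labels, empty ensembles (a species
none of whose candidates beats random is flagged, excluded from
stacking, and reported with NaN metrics), and all-equal Lee inputs
(rescale maps to zeros) are each handled explicitly. All stochastic
stages take explicit seeds derived from one master seed via
`numpy.random.SeedSequence`, and a run manifest records the config hash
and every per-stage seed; re-running a manifest reproduces metrics
byte-for-byte.

## Known limitations

- The Maxent-style learner is a penalized logistic approximation using
  low-order feature classes; it is not a re-implementation of the
  reference Maxent software (no hinge/threshold features, no clamping).
- Cross-technique weights use technique-level cross-validated Somers' D;
  equal weighting is available via configuration.
- The spatial-weights scheme and permutation design for the Lee test are
  defensible defaults, not field-calibrated choices; both are
  configuration options recorded in output metadata.
- Raster I/O is the plain-text ESRI ASCII grid; CRS metadata beyond the
  affine grid origin/cell size is passed through by convention only.
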