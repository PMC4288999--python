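# Methods

This note documents the models, defaults and design choices behind
`traitshift`, and what the synthetic experiments do and do not demonstrate.

## Scope and model chain

The pipeline estimates the *direction* of community-weighted mean trait
(CWMT) change under a climate scenario, not absolute abundances or biomass.
The chain is: presence-only suitability per species per abundance class →
weighted-average relative abundance → allometric biomass weighting → CWMT
and categorical biomass profiles per wetland type and vegetation layer →
K-means regionalization of community change → leave-one-out species
contributions.  Dispersal, establishment, competition and land-use change
are outside the model: per-cell shares express environmental suitability,
not realized local communities.

## Maximum-entropy SDM

The estimator is a minimal presence-background maximum-entropy model
(the Maxent family): q(x) ∝ exp(λ·f(x)) over landscape cells, maximising
the L1-penalised log-likelihood of the presences against the background.

* **Features.** Linear and quadratic terms per continuous layer, one
  indicator per categorical code, standardized on the background.  This is
  sufficient for unimodal (Gaussian) niche responses — in 1-D the true
  conditional density is inside the model class — and deliberately omits
  hinge/product/threshold features, cross-validation and clamping
  diagnostics.  Zero-variance features are dropped with a logged warning.
* **Optimisation.** λ is split into positive and negative parts
  (λ = u − v, u, v ≥ 0), which turns the L1 penalty into a smooth bound-
  constrained problem solved exactly by L-BFGS-B.  The objective is concave;
  convergence is declared when the subgradient optimality residual is below
  tolerance (default 1e-6), and non-convergence is flagged on the model,
  never silent.
* **Regularization.** One global β per standardized feature, default 0.1
  for pipeline fits.  The niche-recovery experiment uses the usual
  sample-size scaling β = 1/√m (m = number of presences, so β ≈ 0.071 at
  m = 200): at m = 200 a fixed β = 0.1 visibly biases the implied niche
  optimum (median error ~0.13 niche breadths vs ~0.07 with scaled β).
* **Background.** Every valid cell when the grid has ≤ 1e5 of them,
  otherwise a seeded uniform sample of 10 000.  Presence cells are part of
  the background (standard Maxent convention).
* **Output scales.** `raw` sums to 1 over the background (a probability
  distribution over cells); `logistic` is the entropy-calibrated transform
  1 − exp(−e^r·raw·N_bg) with r the mean of λ·f over the training
  presences — monotone in raw, in (0, 1) up to floating saturation at 1.0.
  Which scale the original analyses used is not documented; `logistic` is
  the pipeline default, and the choice does not affect the *sign* analyses
  that are this package's purpose so long as one scale is used throughout.
* **Minimum data.** A species × class combination needs ≥ 5 presence
  records (`min_presences`); classes below that are treated as absent and
  their weight is dropped from the abundance normalizer.

## Relative abundance and allometry

Class probabilities p₁, p₂, p₃ (single / frequent / dominant) combine as
A = (w₁p₁ + w₂p₂ + w₃p₃)/(w₁+w₂+w₃) with weights (0.01, 0.1, 1).  Whether
the original weighted average was normalised is not documented; the
normalizer is a config switch (`convention: normalized | sum`), and
relative-biomass shares — hence all CWMTs — are invariant to it, since it
cancels in the per-cell normalisation.

Canopy height converts to maximum potential biomass density as
B_max = 1.769e5·(H/b)^(−0.757/a) (non-tree a = 0.264, b = 2.58; tree
a = 0.345, b = 3.71), implemented exactly as printed.  Note the printed
exponent is negative, so B_max *decreases* with height and the prefactor
(the value at H = b) is physically enormous; since only relative biomass
shares enter the CWMT, any common factor cancels and the ranking between
species is what matters.  A second mode (`allometric_mode: derived`)
implements B = c·(H/b)^((1+d)/a) — biomass density as individual mass ×
maximum density from the two underlying scaling laws, increasing in height
— for sensitivity analysis.  The default is the printed form.

Shares are share_s(x) = A_s·B_max(H_s) / Σ_{s'} A_{s'}·B_max(H_{s'}),
accumulated in sorted species order so results are bit-identical under any
pool ordering.  Cells with zero denominator are masked rather than set to a
uniform community.

## CWMT, pools and contributions

CWMTs are computed per (wetland type × vegetation layer) pool: the field
layer pools pteridophytes, graminoids and herbs; the shrub layer pools
shrubs.  Mosses never enter a pool (no trait or size data); trees are
summarised per species.  A species may belong to several wetland types and
then appears in each pool.  A cell masked in any input is masked in every
derived surface for that pool.

Categorical traits are summarised as biomass-proportion profiles over their
levels; species with an unknown level are excluded and the remaining shares
renormalised (count logged).  Level deltas sum to zero by construction.

Regional summaries are unweighted means (every cell counts equally; sd is
the population sd).  The species contribution score is

score_s = mean_cells (ΔCWMT₋s − ΔCWMT)² / var_cells(ΔCWMT),

where ΔCWMT₋s removes s and renormalises the remaining shares.
"Standardized" is interpreted as division by the spatial variance of the
full change — scale-free and comparable across traits; a species with zero
share everywhere, or whose trait equals the pool CWMT everywhere, scores
exactly 0.  If the full change has zero spatial variance the score is 0
when the leave-one-out change is also unchanged and infinite otherwise.

## Phylogenetic imputation

Each continuous trait is modelled independently as Brownian motion on the
tree: tip covariance σ²C with C the shared root-to-MRCA path lengths.
(μ, σ²) have closed-form GLS maximum-likelihood estimates (ML, not REML —
the bias is immaterial for imputation at these sample sizes), and missing
tips get the conditional MVN expectation given the observed tips, with the
conditional SD reported per imputed value.  SLA, CH and RD are fitted on
the log scale (sizes are log-normal-ish) and back-transformed; the reported
conditional SD for those traits is on the log scale.  Observed entries are
returned bit-exact.  Categorical traits are never imputed; unknown levels
propagate and are excluded from profiles.  Multivariate trait covariance is
out of scope.

## Regionalization

Cells are clustered on raw per-species share changes (future − current):
all columns share units (proportions), so no standardization is applied.
From-scratch Lloyd's K-means with k-means++ seeding, n_init = 10 restarts,
tol = 1e-6 relative SSE, max 300 iterations; the within-run SSE is asserted
non-increasing.  Empty clusters are refilled with the point farthest from
the centroid of the largest cluster.  Labels are renumbered by descending
cell count with centroid-lexicographic tie-breaks, so region 1 is always
the largest.  K defaults to 5 and is a parameter; whether clustering should
be pooled across wetland types or stratified is not documented in the
source analyses — pooled raw changes were chosen here.

## Synthetic data: what it emulates, and what it does not

* **Landscapes.** Continuous layers are Gaussian white noise low-pass
  filtered with a Gaussian kernel (correlation length in cells), then
  standardized to zero mean, unit variance — spatially autocorrelated like
  climate rasters.  (With `standardize=False` the raw filtered field is
  returned, whose variance vanishes as the correlation length grows; the
  two behaviours cannot coexist, so standardization is a flag.)
  Categorical layers bin an independent smooth field into quantile classes,
  giving contiguous patches.  Grid convention: row-major, 0-based, origin
  at the upper-left, half-open cell extents.
* **Species.** Gaussian niche per continuous layer (optimum uniform in the
  observed range, breadth 0.5–1.5 layer sd), per-code multipliers on
  categorical layers, maximum local abundance uniform in [1, 10].
* **Surveys.** Sites are sampled without replacement; detection probability
  equals normalized abundance (presence-only semantics: commoner species
  are recorded more often), and the recorded class thresholds normalized
  abundance at (0.1, 0.5].
* **Traits.** Brownian motion on a random pure-birth tree (branch lengths
  floored at 0.01 so the tip covariance stays numerically non-singular);
  size-like traits optionally exponentiated; missingness uniform at random
  with ≥ 2 observed tips guaranteed per trait.  Categorical traits are
  assigned deterministically per plant functional group, so categorical
  profiles have a known ground truth.
* **Scenario.** Additive offsets on climatic layers only; the demo default
  (+0.5 sd on one layer) is a mild, single-layer analogue of a
  multi-predictor scenario.

Passing tests on these data show the *estimators* recover the structure
they assume: they do not validate niche shapes, detection models or
abundance-class semantics of any real survey protocol, and field data
(spatially biased sampling, correlated predictors, non-Gaussian responses)
will be harder in ways the generator does not emulate.

## Validation experiments (problem sizes)

The experiments in `traitshift.validation` were sized to run in seconds to
a few minutes on one CPU: niche recovery uses 100 replicates of a 40×40
grid with 200 presences; the constructed-sign experiment a 32×32 grid with
20 species surveyed at every cell; region recovery 240 cells in 4 groups
separated by 5 within-group sd; rate recovery 500 replicates at 64 tips.
The constructed-sign experiment spaces niche optima evenly across the
central (q10–q90) realized layer range with one common breadth and ties SLA
affinely to the optimum: this makes the suitability ratio of any two
species monotone in the layer, so an upward shift must favour higher-SLA
species in every cell — the sign is known by construction.  With unequal
breadths a narrow low-optimum species can genuinely gain at trailing-edge
cells, and optima in the rarely-realized tail yield unconstrained fits;
both effects are real and reappear on less constructed inputs.

## Numerical choices

* ESRI ASCII is the only required raster dialect (pure text, diffable);
  read(write(x)) is exact at the written precision (%.10g).
* Near-singular phylogenetic covariances get a relative jitter of 1e-10 on
  the Cholesky fallback; conditional variances are clipped at 0.
* Share sums are validated to 1e-6; partition-of-unity and delta-sum
  invariants hold to 1e-12 in tests.
* All generators and fits are deterministic given their seeds; the pipeline
  derives named stage seeds from one master seed, and a rerun with an
  identical config reproduces identical output checksums.

## Known limitations

* Linear+quadratic features cannot represent the ring-shaped occurrence
  geometry of the lower abundance classes of a 1-D niche; those models are
  misspecified by design and carry small weights (0.01, 0.1) in the
  abundance average.
* The logistic output saturates for strongly-fitted models, compressing
  differences among highly suitable cells.
* Univariate imputation ignores trait–trait correlation, which real trait
  databases could exploit.
* The contribution score divides by the spatial variance of the full
  change; for near-constant change surfaces it is numerically unstable by
  construction (documented above).
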