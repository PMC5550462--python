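# Methods

This note documents the models, conventions and design choices behind
`estuarsens`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Trait categories and relative taxa richness

Species sensitivity is summarized by three ordered-categorical traits:
intrinsic extinction vulnerability to fishing (an aggregate 0–100% score
built from life-history and ecological parameters), resilience (minimum
population doubling time in years — shorter is more resilient), and maximum
body length. Published bin edges are ambiguous where ranges touch ("0–30%"
vs "30–40%"; "1.4–4.4 yr" vs "4.5–14 yr"). The conventions fixed here, and
enforced by exhaustive boundary-scan tests, are:

* vulnerability: [0, 30) Low, [30, 40) Low-Moderate, [40, 60) Moderate-High,
  [60, 70) High-Very High, [70, 100] Very High;
* resilience: (0, 1.4) High, [1.4, 4.5) Medium (the printed 4.4–4.5 gap is
  resolved into Medium), [4.5, 14] Low, (14, ∞) Very Low;
* size: (0, 15) small, [15, 50) medium, [50, 100] large, (100, ∞) very
  large.

A sample's *relative taxa richness* per category is the category count
divided by, per the literal published definition, the **total** observed
richness — so categories of one trait sum to below 1 when some taxa lack the
trait. A `known-only` denominator mode (proportions sum to exactly 1) is
offered as a flagged option since the original accounting is not fully
specified. Taxa resolved above species level with known traits are treated
like species.

## Influence radii, buffer statistics and composites

Each ecosystem's influence radius around an estuary mouth follows a
percentile ladder of its size driver over the whole estuary table:
continental shelf width → 20/40/125/440/600/980 km, estuary area →
1/5/10/30/40/265 km, drainage-basin area → 15/35/85/270/315/1345 km, at the
25/50/75/90/95/100th percentiles (linear-interpolation quantiles). The
binning rule — not stated in the source material — is "first break ≥ value",
ties to the smaller radius, which is monotone and idempotent.

Buffer membership is by cell-center Euclidean distance (inclusive) on the
equal-area plane; the mean uses an exactly rounded sum (`math.fsum`), so it
is bit-identical to any enumeration oracle regardless of summation order.
Masks: `H_marine` averages the marine-impact field over continental-shelf
cells; `H_estuary` averages population density unmasked (land and water "in
and around" the estuary); `H_freshwater` averages the river-threat field
over land/freshwater cells. An empty buffer∩mask yields a missing value with
a logged warning — never a silent zero.

`H_mean` is the arithmetic mean of the three raw pressures. `H_weighted_mean`
weights `H_marine`, `H_estuary`, `H_freshwater` by the sample's marine,
resident and freshwater guild fractions, and applies the **diadromous**
fraction to `H_mean`, since diadromous fish use all three ecosystems. This
makes the weighted mean partially self-referential; it is implemented
literally as defined rather than "corrected", and the explicit
sum-of-weights denominator tolerates rounding in guild fractions.
Composites are computed on raw H; all five variables are then
log(x+1)-transformed and min–max scaled to [0, 1] over the full table
(normalizing after compositing matches the way the five variables are
reported side by side).

Protection coverage uses the same centers and radii: percent = protected
cell area / *eligible* (mask-passing) cell area, plus km². Selections:
`PA_all` (any protected label) and `PA_I_IV` (strict IUCN I–IV only), so
`PA_I_IV ≤ PA_all` holds identically. Variants: marine (shelf mask), estuary
(no mask — at ≤265 km radii the deep-ocean contribution is rarely binding),
freshwater ("everything except marine cells", the minimal literal reading of
an excluding-the-marine-ecosystem buffer). Real protected-area polygons
would be rasterized onto the shared grid; the rasterized layer is the
interface, and polygon ingestion is a documented extension point.

## Statistical layer

**Transforms.** Strictly positive continuous predictors (productivities,
chlorophyll, areas, widths, effort) are log(x+1)-transformed; temperature
and the 1..k ordered codes stay raw. Ordered factors (tidal regime
micro/meso/macro → 1/2/3, estuary type temporarily-open/open → 1/2, salinity
regular/regular-hyperhaline/hyperhaline → 1/2/3) enter as their integer
codes — a linear contrast, matching the single signed coefficient reported
per ordered predictor. Unordered factors (continent, realm) enter as grouped
dummy blocks: one LMG group, one subset-inclusion unit, no per-level
importance. Latitude, mouth width and basin area are excluded from models
for collinearity (with temperature and estuary area) and kept only in
correlation tables. Sampling effort (log total sampled area) is forced into
every model. Nearly aliased design columns are dropped by a Gram–Schmidt
scan seeded with the intercept, and each drop is logged.

**Correlations.** Pairwise Pearson r on pairwise-complete rows, two-sided
p-values from the t-transform with n−2 df, with an `ns` mask at α = 0.05; no
multiple-testing correction is applied, matching the source analysis.

**LMG importance** (linear models only): a predictor group's share is its
R² increase averaged over all orders in which the groups can enter,
computed over the 2^g subsets with the combinatorial weights
k!(g−1−k)!/g! rather than the g! orderings (capped at g ≤ 15). Shares are
non-negative on full-rank designs and sum to the full-model R²; tests verify
exact agreement with an explicit all-permutations oracle.

**All-subsets importance**: every candidate subset (plus intercept and
forced terms) is fitted; Akaike weights use AICc by default (plain AIC is a
configurable alternative — "information criterion" alone underdetermines the
choice and AICc is the safer small-sample default). I(predictor) is the sum
of weights of models containing it; forced terms have I = 1 by construction.
Model-averaged coefficients are *conditional* (averaged over the models
containing the term), which preserves the sign interpretation. A subset
whose fit fails is dropped with a warning and the weights renormalized.

**Mixed models.** Samples nest in estuaries, so the mixed formulation adds a
per-estuary random intercept. Model comparison across fixed-effect sets uses
ML (REML likelihoods are not comparable across fixed structures); final
reported fits use REML. Fitting is by statsmodels `MixedLM` where it
converges; the all-subsets scan, and any fit where the general-purpose
optimizer fails (common with many singleton groups), use an exact
concentrated-likelihood evaluator specialized to the single random
intercept: for a fixed variance ratio λ = σ²_u/σ²_e the GLS solution and
profiled σ² are closed-form from per-group sufficient statistics, leaving a
1-D bounded optimization over log λ (with λ = 0 checked explicitly). The
evaluator is validated against `MixedLM` ML/REML estimates in the tests.
Mixed-model AICc counts fixed coefficients plus the two variances. R² pair
by variance decomposition: marginal = var(Xβ̂)/(var(Xβ̂)+σ²_u+σ²_e),
conditional adds σ²_u to the numerator; marginal ≤ conditional always. (Some
published table captions swap the marginal/conditional labels; the
conventional variance-decomposition definitions are used here.)

Proportion responses are modelled with Gaussian errors untransformed — the
convention of the analysis being reproduced; results near the 0/1 boundary
should be read with that in mind. The reporting view flags predictors with
linear-model importance I > 0.5.

## Synthetic worlds

The generator emulates a compiled global database plus its gridded layers,
with known structure:

* **Geometry.** A square-cell equal-area plane (default 100×100 cells of
  20 km). Rows below a coast line are ocean — a 150 km shelf band, then deep
  ocean — and rows above are land/freshwater; every estuary mouth sits on the
  shelf/land interface so no buffer is empty by construction (empty buffers
  are still tested explicitly).
* **Environment.** Latitude ~ U(−62, 62); SST decreases ~0.37 °C per degree
  of |latitude| plus noise; terrestrial NPP peaks at the equator;
  chlorophyll, shelf width, estuary and basin areas are lognormal; tidal
  regime, estuary type and salinity type are categorical draws; continent
  (6 levels) and realm (9 levels) follow longitudinal bands of the plane.
  The plane is a stand-in for a projected surface, not a globe, so latitude
  is a covariate rather than a coordinate.
* **Species pool.** A Gaussian copula (latent correlations +0.5/+0.6/+0.5
  among vulnerability, doubling time and size) drives inverse-CDF draws
  through piecewise-uniform bin mixtures, so known-trait bin frequencies are
  exact multinomial samples of the renormalized targets while traits covary
  positively in rank (bigger fish: more vulnerable, slower-doubling; the
  stated direction, with a chosen magnitude of Spearman ≈ 0.5–0.6). Default
  targets are the observed global category means (vulnerability
  40/22/23/6/4%, resilience 32/50/8/2%). Those printed means fall short of
  100% by exactly the missing-trait share, so the default MCAR missing
  fraction per trait is that deficit (5% vulnerability, 8% resilience, 5%
  length): whole-pool frequencies with missing taxa in the denominator then
  reproduce the printed values, which is what the calibration tests check.
* **Assemblages.** Each pool species enters a sample independently with
  probability logistic(α_guild + Σ β·driver·1[category] + γ·(log effort −
  log effort_ref)). Guild baselines put inclusion around 10–15%; the
  marine-guild logit gains connectivity bonuses with tidal regime and open
  estuary type. Planted effects (β on centered drivers) are recorded in
  `truth.json` for recovery scoring. Multiple surveys of one estuary differ
  only in effort and random draws. Efforts are log-uniform over
  10³–10⁵ m².
* **Pressure fields** are moving-average-smoothed white noise (uniform
  kernel of half-width = the correlation range, a deliberately simple
  patchiness model), restandardized to the requested mean/sd and clipped at
  0. **Protected areas** grow as random contiguous patches to an exact
  coverage cell count; strict IUCN I–IV labels are assigned patch-by-patch
  with a per-cell top-up to the exact strict fraction.
* **Determinism.** One world seed fans out to per-stage child generators via
  `SeedSequence.spawn`; identical config + seed gives byte-identical
  outputs.

What the generator does *not* emulate: realistic coastline geometry, species
interactions or dispersal limitation (any species can appear anywhere),
abundance (occurrence/richness only), temporal dynamics, and spatially
structured survey bias. Passing tests therefore demonstrate correctness of
the accounting and the estimators under a clean, known data-generating
process — not robustness to the messiness of real compiled survey data.

## Problem sizes and numerical choices

The reference study conditions used by the test suite and acceptance script
are 150 estuaries / 300 samples / 800 species worlds (25 replicates for
planted-effect recovery, with a +0.2 per-°C logit effect of SST on the
low-vulnerability category), 100 groups × 5 replicates for mixed-model
variance recovery, 2000 null simulations at n = 50 for the Pearson type-I
check, and 30 replicate worlds for generator calibration. Calibration is
judged on per-category z-scores with a Šidák-controlled family threshold
(nine categories are compared at once; uncorrected per-category 2-SE bands
would falsely fail a perfect generator about a third of the time) plus an
aggregate mean-|z| bound.

Other numerics: quantiles use linear interpolation between order statistics;
OLS fits use `lstsq` on the explicit design (not normal equations); AICc is
+∞ when n ≤ k+1 so such models drop out of the weights; the mixed profile
optimization searches log λ ∈ [−12, 8] with the λ = 0 boundary evaluated
explicitly, and an estuary-variance estimate at that boundary is flagged
singular, as is any grouping with no replicated groups (the variance is then
not separately identifiable). Min–max normalization refuses constant
columns by name rather than emitting NaNs.

## Known limitations

* The estuary-variant protection buffer is unmasked and the freshwater
  variant is "all non-marine cells"; both are minimal readings of loosely
  specified geometry.
* Ordered factors as integer codes assume equal spacing between levels.
* Gaussian errors on proportion responses ignore heteroscedasticity near the
  boundaries; a logit option exists but is off by default to match the
  reproduced analysis.
* LMG and all-subsets scans are exponential in the number of groups
  (capped at 15); realm/continent blocks count as single units.
* The conditional model-averaged coefficient is reported for sign and
  magnitude; it is not a shrinkage estimator.
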