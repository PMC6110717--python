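# Methods

This note records the models implemented in `conflictscope`, the defaults
and the reasoning behind choices the protocol left open.

## Coordinate and raster conventions

All coordinates are planar kilometres with the origin at the lower-left
corner of the study rectangle. Rasters are rectangular grids with 0-based
row-major indexing and row 0 at the bottom; a cell covers a half-open
square and a point maps to its cell by floor division, so the
raster↔point mapping is unambiguous and exactly invertible at cell
centres. Nodata cells (marker −9999) are excluded from every statistic.
On disk, rasters are single-band float32 GeoTIFFs written through
`tifffile` with ModelPixelScale/ModelTiepoint/GDAL_NODATA tags (rows
flipped to the top-first order GeoTIFF expects).

## Synthetic data generator

The generator emulates a forest-edge conflict landscape with known ground
truth; it reproduces the *statistical* features the pipeline is sensitive
to, not the geography of any real region.

* **Covariates.** Rivers and roads are random polylines, forest a
  thresholded smoothed noise field; the three distance rasters come from
  exact Euclidean distance transforms. Population, farmer density,
  occupancy and connectivity are Gaussian-smoothed white noise rescaled
  to their ranges (smoothing sd 4 cells by default). Only the spatial
  autocorrelation of these fields matters for testing; realistic
  hydrology, road networks or circuit-theory connectivity are explicitly
  out of scope.
* **Encounters.** Event intensity is
  inverse-logit(β·z-scored covariates) × (Gaussian mixture over source
  territories + a uniform floor of 0.05 of the mixture peak). The floor
  lets incidents occur across the whole landscape, matching the premise
  under which background pseudo-absences are drawn; with no sources the
  term is exactly 1 so a zero-β configuration is uniform. Default truth:
  three sources with 15 km scatter; β positive on population, occupancy
  and connectivity and negative on the distances to rivers and forest.
  Categories are drawn from the 106:83:12:27 mix (sighting, livestock
  attack, attack on a person, removal); `exact_mix=True` apportions the
  counts exactly (largest remainder) for the packaged 228-event reference
  record. Dates are uniform over a 13-year window — enough to exercise
  the 1-month deduplication and 6-month linkage rules without modelling
  seasonality.
* **Survey.** Ten psychometric items share one latent pro-conservation
  factor (loadings 0.3–0.7) and four management-scenario items share a
  second, correlated factor with loadings 0.38/0.64/0.93/0.79, so the
  scale diagnostics (α, KMO, one-factor solution) see a realistic
  structure. Four items are reverse-keyed on disk and re-oriented (6 − x)
  during preparation. The 3-category tolerance response follows a
  multinomial logit on the z-scored items, the scenario mean and the
  z-scored risk value at the respondent's village; slopes echo the
  magnitudes and signs of the study's averaged coefficients (including a
  negative geographic-profile effect, −0.132/−0.245). The two intercepts
  (1.047, −0.501) were calibrated once by fixed-point iteration so the
  long-run analysed shares reproduce the 28.1/48.0/19.4 % margins after
  4.5 % don't-know and 1.2 % missing responses are injected; they are
  frozen constants, not fitted at run time. What the generator does *not*
  emulate: demographic structure of respondents (sex/age/ethnicity are
  decorative draws with the study's margins but no effects), item
  missingness, and interviewer or village-level random effects — so
  passing tests demonstrate the estimators recover known effects under
  clean conditions, not robustness to those complications.

## Geographic profiling

Events x_i follow a Dirichlet-process mixture: partition c ~ CRP(α),
cluster sources μ_k ~ N(c₀, τ²I), x_i | μ_k ~ N(μ_k, σ²I). A collapsed
Gibbs sampler reassigns each event to an existing cluster with
probability ∝ n_k × posterior-predictive density, or to a new cluster
∝ α × prior predictive. Defaults where the protocol is explicit:
50,000 samples per chain, 10 chains, 10,000 burn-in. Defaults the
protocol leaves open (all configurable and logged): α = 1 (one expected
extra cluster per log-n events), prior centre = data centroid,
τ = maximum data extent (diffuse, data-scaled), storage thinning 10 to
bound memory of stored partitions.

σ is sampled by griddy Gibbs over 50 log-spaced values on
[0.1, 2 × data extent]: given the partition, the cluster means are
integrated out analytically and σ is drawn from its discretised
conditional posterior. Exact duplicates of event coordinates drag σ
toward zero, so σ estimation is two-stage: stage 1 fits σ on the unique
points only and reports the posterior mean; stage 2 re-profiles all
points with σ fixed. Fewer than two unique points leaves σ unidentified
and is an error.

Chains are pooled without convergence gating, but split-R̂ of the
cluster count is computed, logged and raised as a warning above 1.1 —
short exploratory chains will trip it, which is the intended signal to
lengthen the run.

The geoprofile surface is the posterior-mean source density: per stored
draw, Σ_k n_k/(n+α) · N(cell | posterior mean and variance of μ_k) +
α/(n+α) · N(cell | prior), renormalised to sum to 1 over valid cells.
The search order ranks cells by descending probability with mid-ranks on
ties (unbiased hitscores on flat regions). A target's hitscore counts
strictly better cells, half of the equal-valued others, and its own
cell, over all searchable cells; the Gini evaluates
2∫(F(x) − x)dx exactly from the hitscore step function, which reduces to
1 − 2·mean(hitscore).

## Risk ensemble

The member set is five binomial families: unpenalised logistic
regression; logistic regression on a cubic-spline basis expansion
(5 knots per covariate) as the additive member; a 200-tree random
forest; an RBF-kernel SVM with sigmoid probability calibration; and
gradient-boosted trees — library defaults otherwise, with fixed seeds,
since the pipeline contract does not depend on hyperparameter tuning.
Screening uses mean held-out AUC over ten stratified 70/30 splits with
the > 0.70 threshold. TSS weights are computed in-sample after the full
refit (the protocol does not say whether TSS is cross-validated; the
in-sample choice matches the behaviour of the ensemble tooling the
original analysis used, and the value is logged). Scaling parameters are
frozen at fit time and reused for prediction to prevent train/predict
skew. Pseudo-absences are uniform over "farmland" = valid cells with
forest cover below 0.5 (the exact farmland definition is not stated;
the threshold is configurable). The ensemble AUC is reported both
TSS-weighted and equal-weighted, since the published weighted average
does not state which was used.

## Tolerance models

Multinomial logits are maximised by Newton iterations (via statsmodels)
with reference category "reduce/eradicate"; standard errors come from
the inverse observed information. K counts all estimated parameters:
2 × (1 + predictors). AICc = −2ℓ + 2K + 2K(K+1)/(n−K−1); the correction
toggle defaults to on and errors when n ≤ K + 1. Ethnicity is one-hot
encoded against the largest group. The candidate set defaults to the
four named models (social; +geoprofile; +ensemble probability;
+landscape covariates); an all-subsets generator is available behind a
4096-model cap for importance analyses over larger rosters. Averaging is
conditional (subset) over the ΔAICc < 2 confidence set with
unconditional standard errors √(Σ wᵢ(seᵢ² + (βᵢ − β̄)²)); full-set
averaging is available by flag. The geoprofile enters as the z-scored
surface value at the village centroid — a monotone function of source
density; using a rank transform instead would change coefficients but
not model ordering in our simulations.

Scale diagnostics: Cronbach's α from item vs total-score variances; KMO
from squared zero-order vs partial correlations (partials from the
inverse correlation matrix); the factor solution is the first
eigenvector of the item correlation matrix scaled to loadings, with
variance explained λ₁/k — a principal-component factoring, adequate for
a single dominant factor.

## Prioritisation

Tolerance is coded 1/2/3 and summarised per village by the mean (the
protocol wavers between "below average" and "below median" tolerance;
the split uses medians, and the mean summary per village is the default
with a median option). Classification: high = risk > median and
tolerance < median; medium = risk > median and tolerance ≥ median;
low = risk ≤ median. If every risk score ties, all villages fall in the
low class (documented rule, warned). A month is 30 days for all gap
arithmetic. Deduplication is per village *and* category — the published
rule does not say whether a sighting suppresses a nearby-in-time attack,
and keeping categories separate preserves escalation chains. Accounting
reports attack/removal shares against both the study-village and the
all-encounter denominators, since the two headline figures in the source
analysis use different denominators.

## Numerical choices and problem sizes

Sampling uses `numpy.random.default_rng` throughout; chains take
sub-seeds from a `SeedSequence` spawn. Category sampling, cell sampling
and within-cell jitter are all driven by the stage seed, making every
artifact bit-reproducible from config + seed. Tests and the acceptance
script run the MCMC at reduced sizes (400–1200 samples, 2–4 chains,
thinning 5–10) and the ensemble at 400–2000 pseudo-absences with 2–5
cross-validation replicates; these sizes were chosen as the smallest at
which the recovery checks (two-source separation, σ window, Gini
discrimination, coefficient coverage) are stable across seeds. The
default configuration retains the full published protocol.

## Known limitations

* The DPM kernel is isotropic Gaussian; anisotropic or heavy-tailed
  dispersal, and spatiotemporal profiling, are out of scope.
* Cross-validation splits are random, not spatially blocked, so member
  AUCs are optimistic under strong spatial autocorrelation — consistent
  with the protocol being reproduced.
* The σ griddy-Gibbs grid bounds ([0.1, 2 × extent]) truncate the
  posterior for pathological inputs (e.g. two points metres apart).
* Ordered-logit refits, item imputation and Bayesian multinomial
  alternatives are deliberately not implemented.
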