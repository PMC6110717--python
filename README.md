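# conflictscope

Tools for socio-ecological analysis of human–carnivore conflict, written
for conservation scientists and quantitative ecologists who need to turn a
point record of wildlife encounters and a village questionnaire survey
into spatial risk maps, validated search priorities, and a ranked list of
settlements for intervention.

The package couples four analyses that are usually run in isolation:

1. **Ensemble encounter-risk mapping.** Encounter locations (presences)
   are contrasted with uniform background pseudo-absences drawn from the
   farmland extent. Covariates are 3.25 km buffer means of landscape
   rasters, z-scored and screened for collinearity (|r| < 0.7, VIF < 3).
   Five binomial learner families (GLM, spline-basis GAM, random forest,
   kernel SVM, boosted trees) are cross-validated on 70/30 splits x 10;
   members with mean held-out AUC > 0.70 are refit and combined with
   weights proportional to their true skill statistic,
   TSS = max_t (sensitivity + specificity − 1). Permutation importance is
   the Pearson r between ensemble predictions before and after permuting
   a covariate (low r = important).
2. **Geographic profiling.** Events are modelled as a Dirichlet-process
   mixture of bivariate-normal sources: a Chinese-restaurant-process prior
   with concentration α partitions events into clusters, sources carry a
   conjugate N(c, τ²I) prior, and events scatter with isotropic sd σ (km).
   A collapsed Gibbs sampler (with a griddy-Gibbs step for σ; two-stage
   fitting on unique points to avoid the duplicate-point σ→0 pathology)
   yields a *geoprofile*: a surface of source probability that sums to 1
   and is searched in decreasing order. Search skill is scored by
   hitscores (area fraction searched before a target is reached) and a
   Gini coefficient, 1 = perfect search, 0 = random.
3. **Tolerance modelling.** The 3-category population preference
   (reduce/eradicate, same, increase) is modelled by multinomial logistic
   regression on psychometric items (affect, attitudes, norms, beliefs,
   trust; scale quality checked by Cronbach's α, KMO and a one-factor
   solution) with village-level risk covariates. Candidate models are
   ranked by AICc; coefficients are model-averaged over the ΔAICc < 2
   confidence set, term importance sums Akaike weights, and model pairs
   are contrasted by evidence ratios exp(ΔAICc/2).
4. **Prioritisation.** Villages are scored by buffer-mean risk and mean
   coded tolerance (1/2/3) and split at the medians: high = risky and
   intolerant, medium = risky but tolerant, low = below-median risk.
   Encounter chains (events < 6 months apart in one village, after
   1-month deduplication) and per-class attack/removal accounting quantify
   what earlier intervention could have averted.

A synthetic-data module generates landscapes, encounters, villages and
questionnaire responses with known ground truth, so the entire pipeline is
testable end to end without any data download.

## Worked example

Profile synthetic sightings and ask how quickly the profile finds the
held-out attacks:

```python
import conflictscope as cs

landscape = cs.gen_landscape(cs.LandscapeConfig(extent=(120, 120), cell_size=2.0, seed=7))
truth = cs.TruthParams()
encounters = cs.gen_encounters(landscape, truth, 228, seed=8, exact_mix=True)

sightings = encounters[encounters.category == "sighting"][["x", "y"]]
attacks = encounters[encounters.category.isin(
    ["livestock_attack", "human_attack", "removal"])][["x", "y"]]

config = cs.DPMConfig(samples_per_chain=1000, burn_in=300, n_chains=4,
                      thin=5, grid=landscape.grid, seed=9)
result = cs.validate_by_category(sightings, attacks, config)
print(f"sigma_hat = {result['sigma_hat']:.1f} km")
print(f"Gini      = {result['gini']:.3f}")
for frac, found in result["search_fractions"].items():
    print(f"found {found:.0%} of attacks searching {frac:.0%} of the area")
```

Output:

```
sigma_hat = 19.0 km
Gini      = 0.496
found 49% of attacks searching 15% of the area
found 66% of attacks searching 30% of the area
```

σ̂ is the fitted dispersal scale of events around their sources (the
generator placed sources with 15 km scatter plus a diffuse background, so
19 km is a faithful estimate). A Gini of 0.50 means the sightings-trained
profile finds held-out attacks far faster than random search: half of them
within the top-ranked 15% of the study area.

The full pipeline — simulate → geoprofile → risk → tolerance →
prioritize → report — runs from one configuration:

```python
from conflictscope.io import RunConfig, run_pipeline
report = run_pipeline(RunConfig(outdir="run", seed=1, n_respondents=1200,
                                samples_per_chain=1000, burn_in=300,
                                n_chains=4, n_absences=2000, cv_reps=5))
```

writing rasters (GeoTIFF), tables (CSV), villages (GeoJSON) and a
JSON + Markdown report with member AUCs, TSS weights, variable importance,
σ̂, Gini, the AICc comparison table, evidence ratios and the priority
accounting. The same stages are exposed on the command line
(`conflictscope simulate|geoprofile|risk|tolerance|prioritize|all`).

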