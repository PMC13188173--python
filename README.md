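# richscape

Stacked species-distribution-model (SDM) richness mapping with
stratified-heterogeneity and path-model driver attribution — a reusable,
tested implementation of the full analysis chain used in regional studies
of (fruit-)tree species richness, exercised end to end on synthetic
landscapes with known ground truth.

## What it does

Given environmental covariate rasters in four driver groups (climate, soil,
terrain, anthropogenic) and per-species occurrence records, the pipeline:

1. **Suitability modelling** — fits a maximum-entropy (Gibbs) model per
   species: the distribution over landscape cells
   `P(x) = exp(λ·f(x)) / Z` maximizing entropy under the presence sample's
   feature-expectation constraints, with an L1 penalty `β‖λ‖₁`; evaluated
   by replicate hold-out AUC (75/25 split × 10 repetitions).
2. **Variable screening** — per species keeps the top covariates reaching
   95% cumulative contribution (permutation importance), counts
   cross-species occurrence frequency, and prunes pairs with |Pearson r| >
   0.8, keeping the higher-frequency member.
3. **Richness stacking** — binarizes each suitability surface at its
   natural (Fisher–Jenks) breakpoint `T_i` — `B_i(x) = 1` iff
   `P_i(x) > T_i` — and stacks `R(x) = Σ_i B_i(x)`.
4. **Stratified-heterogeneity attribution** — the q-statistic
   `q = 1 − SSW/SST` per discretized factor, pairwise interaction q on
   strata overlays with the standard enhance/weaken taxonomy, and
   group-level interaction matrices (both the combined-strata and the
   mean-pairwise reading).
5. **Path modelling** — collapses each covariate group to a composite
   index (first principal component or mean) and fits the recursive
   standardized system
   `R = β₁T + β₂C + β₃S + β₄A + ε`, `C = γ₁A + γ₂T + ζ₁`,
   `S = γ₃A + γ₄T + ζ₂`, with analytic standard errors, 95% CIs,
   direct/indirect/total effect decomposition, and covariance-based fit
   indices (χ², CFI, NFI, GFI).

A synthetic-landscape generator (spatially autocorrelated Gaussian fields,
Gibbs-law occurrences with known weights, a richness response with known
structural coefficients) makes every stage testable against ground truth
without any data downloads.

## Worked example

```python
from richscape import simulate as sim, maxent, stacking, sem

cfg = sim.LandscapeConfig(shape=(80, 80), n_species=6, n_points=250, seed=42)
data = sim.make_dataset(cfg)

occ = data.occurrences[0]
report = maxent.evaluate_auc(occ, data.env, beta=0.05, split=0.75, reps=10, seed=0)
print(f"{occ.species}: mean test AUC = {report.mean_auc:.3f} (sd {report.sd_auc:.3f})")

model, _ = maxent.fit_species(occ, data.env, beta=0.05)
_, suit = maxent.predict_suitability(model, data.env)
t, meta = stacking.species_threshold(suit, k=2)
print(f"natural-breaks threshold T = {t:.3f} (gvf {meta['gvf']:.3f})")

flat = data.env.pixel_table.index.to_numpy()
resp = data.richness_true.values.ravel()[flat]
idx = sem.build_indices(data.env.pixel_table, data.env.groups, resp, method="pc1")
pm = sem.fit_path_model(idx)
print(sem.path_table(pm).round(4).to_string(index=False))
```

prints

```
species_01: mean test AUC = 0.982 (sd 0.008)
natural-breaks threshold T = 0.420 (gvf 0.790)
                   path  estimate     se  ci_low  ci_high
 climate<-anthropogenic    0.1730 0.0118  0.1498   0.1962
       climate<-terrain   -0.2644 0.0118 -0.2876  -0.2412
    soil<-anthropogenic   -0.0056 0.0125 -0.0301   0.0189
          soil<-terrain    0.0295 0.0125  0.0050   0.0540
      richness<-terrain    0.0969 0.0116  0.0743   0.1196
      richness<-climate   -0.0565 0.0118 -0.0796  -0.0335
         richness<-soil   -0.1400 0.0111 -0.1618  -0.1181
richness<-anthropogenic    0.4337 0.0113  0.4115   0.4558
```

The AUC says this synthetic species is almost perfectly discriminable from
background; the threshold `T` is the Jenks breakpoint used for
binarization; the path table gives the standardized direct effects among
the four driver indices and richness (composite-index proxies attenuate
coefficients relative to the generating values — see `docs/methods.md`).

The same chain runs from the shell:

```sh
richscape all --seed 1 --outdir out/
# or stage by stage: simulate | fit-sdm | select-vars | stack | detect | sem
```

emitting per-species AUC tables, suitability/richness rasters (ESRI ASCII),
factor and interaction q matrices, and the path-coefficient, effect and
fit-index tables, plus a provenance record.

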