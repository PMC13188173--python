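# Methods

This note records the models implemented, the defaults and why, what the
synthetic data do and do not emulate, and the numerical choices a
maintainer would want written down.

## Maximum-entropy suitability model

The model is the Gibbs distribution over background cells,
`P(x) = exp(λ·f(x))/Z`, the maximum-entropy distribution whose feature
expectations match the presence sample's empirical means. We fit the
equivalent penalized likelihood: maximize the mean presence log-likelihood
minus `β‖λ‖₁`. At the optimum the KKT conditions bound every feature's
moment mismatch, `|E_model[f_j] − E_presence[f_j]| ≤ β`, with equality on
active features; this is asserted after every converged fit.

* **Features.** Linear and quadratic transforms of each covariate
  (pairwise products available), min–max scaled to [0, 1] on the
  background. Hinge/threshold/categorical features are out of scope.
  Values outside the training range are clamped after scaling (counts
  logged). Constant covariates are dropped with a warning.
* **Optimizer.** The L1 term is handled by the positive/negative split
  `λ = u − v`, `u, v ≥ 0`, making the objective smooth and
  bound-constrained; L-BFGS-B solves it with monotone decrease over
  accepted iterations. The solver runs essentially to gradient
  convergence (projected-gradient tolerance 1e-8) because the KKT moment
  check needs gradient-level accuracy; `tol` (default 1e-6) is the
  objective-change criterion used to report the stopping reason, and
  `max_iter` defaults to 500.
* **Defaults.** `β = 0.05` on the scaled features; background = all
  non-nodata cells (the synthetic grids have ≤ 10⁴ cells, so no
  background subsampling is needed). Duplicate presence records within
  one cell are collapsed — standard SDM hygiene. Presences must number at
  least 5.
* **Evaluation.** Per replicate the presence cells are split 75/25,
  the model refit on the training part, and AUC computed by the exact
  rank statistic (ties count ½) of test presences against all background
  cells. Ten replicates; mean and SD reported, training AUC alongside.
* **Variable importance.** "Contribution" percentages are permutation
  importance: permute one covariate across the evaluation rows, rebuild
  features, record the AUC drop (mean over `n_perm` permutations, floored
  at 0), normalized to sum to 100. This is a deliberate, openly declared
  replacement for MaxEnt-internal training-path contributions, which are
  tied to a particular training trajectory and not reproducible from a
  model definition. Jackknife leave-one-in/leave-one-out training gains
  (nats above uniform) are provided separately.

## Variable screening

Per species, covariates are ranked by contribution and the minimal prefix
reaching 95% cumulative contribution retained ("reaching" read
inclusively: a prefix summing to exactly 95 qualifies). Occurrence
frequency = number of species selecting the covariate; zero-frequency
covariates are excluded. Collinear pairs (|Pearson r| strictly > 0.8 over
the full pixel table) are processed in descending |r|; within a pair the
lower-frequency covariate is dropped (ties: lower total contribution,
then lexicographically later name), and a dropped covariate cannot
trigger further drops. All tie-breaks are declared so the screen is
invariant to input order; the pruned set is a fixed point of re-screening
and contains no offending pair.

## Thresholding and stacking

`jenks_breaks` is the exact Fisher–Jenks dynamic programme (O(k·n²),
vectorized inner loop): the optimal partition of sorted values into k
contiguous classes minimizing within-class sum of squared deviations.
Above 3000 values the programme runs on a deterministic equal-quantile
subsample of 3000 — for the smooth, dense suitability distributions being
thresholded this moves the breakpoint by at most the local inter-quantile
spacing; exactness tests run at small n against exhaustive enumeration.
Breakpoints are placed midway between the boundary value pair, since the
programme yields a pair of adjacent values, not a point.

Binarization uses k = 2 by default (the minimal reading of "key
breakpoints"; k is configurable and recorded in provenance metadata along
with the break index and goodness-of-variance fit). The threshold rule is
strictly `P > T`; a pixel exactly at the threshold is unsuitable.
Richness is the per-pixel sum of the binary maps under the union-nodata
rule, and conserves: total richness equals the sum of per-species
suitable-cell counts. Pixelwise Pearson correlations of richness with
every covariate are reported sorted descending.

## Stratified-heterogeneity (q-statistic) attribution

`q = 1 − Σ_h N_h σ²_h / (N σ²)` with population variances — the classical
definition; q equals the ANOVA between-strata share and is affine
invariant in the response. Interaction q is the q of the overlay (distinct
label pairs), classified against q(A), q(B) and q(A)+q(B) as
nonlinear-weaken / uni-weaken / bi-enhance / independent /
nonlinear-enhance. Because the overlay refines both stratifications,
q(A∩B) ≥ max(q(A), q(B)) up to rounding.

Defaults: Jenks discretization with k = 5 per factor for single-factor
and pairwise detectors; k = 3 per factor inside group overlays to bound
the strata count; overlay strata smaller than 10 pixels are merged into
the stratum with the nearest centroid in the members' standardized value
space, since tiny strata mechanically inflate q. Circular covariates
(aspect) are discretized into fixed compass sectors rather than by Jenks.
Group-level interaction matrices are emitted under two labelled readings
— q of the overlay of the two groups' combined strata, and the mean of
pairwise cross-group factor interactions — because "average interaction
between groups" is genuinely ambiguous between the two, and they can
differ by a large margin (the combined overlay is a much finer
stratification). A permutation test (`q_significance`, ≥ 99 shuffles,
seeded) is available; the add-one p-estimate `(1+#{q* ≥ q})/(1+n_perm)`
is used.

## Recursive path model

The four groups are collapsed to composite indices (default: first
principal component of the group's standardized variables, sign-anchored
so a configured anchor variable — by default the group's first — loads
positively; standardized mean available). The structural system

    R = β₁T + β₂C + β₃S + β₄A + ε
    C = γ₁A + γ₂T + ζ₁
    S = γ₃A + γ₄T + ζ₂

is recursive, so equation-wise least squares on standardized variables
yields the standardized path coefficients; SEs and 95% CIs are the
analytic OLS ones (optional seeded nonparametric bootstrap). A full
free-loading latent-variable SEM is deliberately out of scope: the
composite-index formulation keeps the estimator transparent and exactly
testable, at the cost of treating loadings as fixed.

Effects: direct = path coefficient; indirect = products along mediated
routes (e.g. T→C→R contributes γ₂β₂); total = direct + indirect, verified
at run time against the reduced-form matrix `(I − M)⁻¹ − I`.

Fit: model-implied covariance `Σ̂ = (I−M)⁻¹Ψ(I−M)⁻ᵀ` (Ψ = exogenous
covariance block plus ML residual variances), ML discrepancy
`χ² = (n−1)·F_ML` with df = 15 moments − 14 free parameters = 1; the
baseline is the mutual-independence (diagonal) model, df = 10.
CFI = 1 − max(χ²−df, 0)/max(χ²_b−df_b, χ²−df, 0), NFI = (χ²_b−χ²)/χ²_b,
GFI = 1 − tr[(Σ̂⁻¹S − I)²]/tr[(Σ̂⁻¹S)²]; all clipped to [0, 1].

Pixels are treated as independent observations, as a conventional
all-pixel fit implies; under spatial autocorrelation the analytic SEs are
optimistic (the effective sample is smaller than the pixel count), which
is why the generator-level CI-coverage checks use white-noise draws where
the nominal level applies.

## Synthetic landscapes

* **Random fields.** White noise smoothed by a Gaussian kernel on a torus
  (stationary by construction), re-standardized. The kernel scale is
  `corr_range/2`, so `corr_range` is the e-folding distance of the
  spatial autocorrelation `exp(−d²/corr_range²)`; `corr_range = 0` is
  exactly white noise. Default `corr_range = 5` cells on a 100×100 grid —
  smooth enough to look like interpolated climate surfaces, rough enough
  that the grid holds many independent patches.
* **Covariate structure.** Terrain and anthropogenic index fields are
  independent; climate and soil indices follow the structural equations;
  each group member is `0.8·index + 0.6·noise`, re-standardized (member–
  index correlation 0.8). Group sizes default to climate 6, soil 4,
  terrain 2, anthropogenic 4; the generating structural coefficients
  default to the standardized values a regional driver analysis of this
  design reports (γ₁ = 0.1558, γ₂ = −0.3624, γ₃ = −0.0319, γ₄ = 0.1162,
  β₁ = 0.2597, β₂ = 0.0548, β₃ = −0.0986, β₄ = 0.3469).
* **Residual scales.** Endogenous noise SDs default to the values that
  leave each standardized endogenous variable at unit variance; the
  richness residual uses the model-implied explained variance.
* **Occurrences.** Drawn with replacement from the Gibbs law over
  non-nodata cells using the same feature construction the fitted model
  uses, placed at cell centres; 300 records per species, 14 species.
  Community weights are sparse (3 active covariates per species,
  N(0, 12²) on scaled features): strong enough that most — not all —
  species are discriminable above test AUC 0.8, the usual situation for
  a multi-species ensemble. A "strongly determined" species in tests
  means a single dominant weight of ~16, i.e. a suitability ratio of e¹⁶
  across the covariate's range.
* **Known-truth richness.** The continuous structural response is
  discretized to integers 0..n_species by equal-count rank binning
  (rank-preserving). This surface exists so the attribution stages can be
  scored against known coefficients independently of the stacking chain.

What the generator does **not** emulate: physical climate/terrain realism,
anisotropy, projections, sampling bias in occurrence records, or spatial
nonstationarity. Consequently, passing tests demonstrate the estimators'
correctness under their stated assumptions, not robustness to the biases
of real occurrence compilations.

Composite-index proxies built from noisy group members (member loading
0.8) attenuate and mix path coefficients relative to the generating index
values — the usual errors-in-variables effect; exact recovery checks
therefore run on the generating indices themselves, while the
pipeline-level fit documents the attenuated values a practitioner would
see.

## Scale and runtime choices

The default landscape is 100×100 pixels (10⁴ cells) with 14 species — the
full pipeline runs in well under a minute on one CPU. Estimator-level
checks use n = 5000 draws (path recovery; 200 replicates for CI coverage)
and n = 10⁵ for fit-index limits. These sizes were chosen so every
distributional claim is sampled well while the whole suite stays fast.

## Degenerate inputs and tie-breaks (summary)

* Constant covariates: dropped (features), dropped with warning
  (screening), error (discretization, thresholding).
* Constant response: q and correlations undefined — error / NaN with
  warning rather than a silent 0.
* Jenks with fewer distinct values than classes: error.
* Points off-grid or on nodata: excluded with a logged count.
* A pixel masked in any layer is masked everywhere (union nodata).
* All tie-breaks (contribution ties, prune ordering, top-3 cut) are by
  covariate name, making every screen deterministic and order-invariant.
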