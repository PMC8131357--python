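# Methods

This note documents the statistical machinery, the synthetic-data model and
its limits, the numerical conventions, and the design choices that were
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Data model and units

The unit of analysis is the *site*, nested in a spatial *block*, nested in
a *study* (one survey campaign with its own methodology). Records are
long-format: one row per (site, taxon) with a non-negative measurement
(abundance count or density) and a sampling effort. The combined land-use ×
intensity class (LUI) — eight land-use types × {Minimal, Light, Intense} —
is the main categorical driver, with `Primary_Minimal` the baseline.
Intensity labels come in two dialects (Light≡Low, Intense≡High); the
alias table lives in one place in `ingest`.

Ingest conventions:

* Sites with unknown land use or intensity, and secondary vegetation of
  indeterminate age, are dropped before anything else.
* Effort is rescaled to max 1 within each study and abundance measurements
  divided by it. Missing effort is treated as the study maximum (no
  adjustment), logged; the raw measurement is kept alongside because
  Chao1's singleton/doubleton counts are defined on counts, not on
  non-integer adjusted values (raw counts are rounded half-up first).
* LUI classes with fewer than `min_sites` sites (default 30) are removed;
  any threshold in (23, 43] reproduces the removal behaviour the design is
  modelled on, and 30 is exposed as configuration. Removing the baseline
  class is a hard error.
* Tropical means |latitude| ≤ 23.4368°, boundary inclusive (the tropic
  line is not otherwise pinned down numerically).
* Covariate grids are plain-text ESRI ASCII rasters. Cells are half-open
  [x, x+cs) × [y, y+cs), row-major from the north-west corner; points on
  the outer east/south boundary map into the last cell. The convention is
  bit-exact on purpose: 5-arc-minute cells are coarse relative to site
  coordinates, so which cell a site falls in must not depend on floating
  point accidents. Grids are summed cell-wise before extraction; models
  use log10(rate + 1).

## 2. Roster construction

Evidence levels (1 strongest): 1 experimental pollination, 2 pollen
carrying, 3 nectar/pollen feeding, 4 non-destructive/non-predatory flower
visitation. Contrary evidence (destructive or predatory visitors — the
ant and crab-spider pattern) makes a *negative* record. Per genus the best
(lowest) positive level wins; genera with only negative evidence go to a
blocklist.

Extrapolation promotes genus evidence to whole groups: a family is wholly
pollinating when ≥ 2 of its immediate sub-lineages contain a confident
genus and no genus in the family is blocklisted; failing that, the same
rule is applied to subfamilies, then tribes (at tribe level the immediate
lineages are genera). "Multiple branches" is operationalised as ≥ 2
distinct immediate child lineages (`min_branches`, configurable) since the
source workflow never quantifies it. A genus with no subfamily recorded is
its own immediate lineage of its family. Negative evidence propagates
up (blocks the containing group) but not down (sibling genera keep their
own evidence). Subtribe is collapsed into tribe: survey tables record no
rank between family and genus, so finer ranks would be untestable.

Merging inserts direct genus entries first, so every genus carries exactly
one confidence, then group entries, then expert edit lists. Expert
removals beat extrapolation but not direct evidence unless they name the
genus itself — removals target "highly unlikely" pollinators, which by
definition lack credible direct evidence; whether the original expert pass
ever overrode direct evidence is unknowable from the record, so this is a
package choice. Compilation is idempotent. Group entries are expanded to
genus sets against the reference taxonomy at compile time (survey tables
carry only family and genus), which is why `compile_roster` and
`filter_records` take the taxonomy as an argument.

The binomial scanner is deliberately dumb: a capitalised token followed by
a ≥3-letter lowercase epithet, genus matched case-sensitively against the
reference list, no fuzzy matching — deterministic by construction. The
published name-scraping tooling it stands in for is out of scope.

## 3. Mixed-model engine

Random effects are intercepts only (study, block-within-study, and for
Poisson models an optional observation-level intercept, OLRE), which is
exactly what this design needs and keeps the linear algebra cheap: with U
the stacked group indicators (n × q) and diagonal G, every likelihood
evaluation reduces to a q × q solve via the Woodbury identity.

* **Gaussian (ML):** residual variance and β profiled analytically;
  Nelder-Mead over the ≤ 2 log variance ratios. The reported coefficient
  covariance uses the bias-adjusted scale RSS_W/(n−p); the log-likelihood
  and AIC use the ML scale. Verified in the tests against a dense-matrix
  likelihood evaluation and against statsmodels `MixedLM` / lme4 `lmer`
  (agreement to printed precision on the shared fixture).
* **Poisson (Laplace):** for fixed variance ratios, (β, u) are maximised
  jointly by penalized Newton (OLRE handled as a diagonal block by Schur
  complement; shrunk working weights μ/(1+γ·μ)); the Laplace-approximate
  marginal log-likelihood is then maximised over the ratios by Nelder-Mead
  with one restart. β's covariance is the (β, v) block of the inverse
  joint Hessian after eliminating the OLRE block. This matches lme4
  `glmer` closely (slope, SEs, variance components, AIC), with one known
  flavour difference: `glmer` optimises the Laplace criterion over (θ, β)
  jointly, whereas here β sits at the joint penalized mode. The
  difference shifts the intercept by ≈ σ²_OLRE/2 in OLRE models and
  cancels exactly in every class-vs-baseline contrast, which is all the
  downstream effect machinery uses.

Convergence: relative tolerance 1e-6, max 500 inner iterations; a variance
ratio pinned at the lower search bound (e^−12) is reported as a singular
fit with that variance 0. AIC comparisons are ML-based throughout (models
differ in fixed effects, so REML-style criteria would not be comparable).
Non-integer Chao1 responses are rounded to the nearest integer and fitted
with the same Poisson spec, a quasi-likelihood reading of the design.

**Overdispersion check.** Without an OLRE this is the standard conditional
Pearson ratio Σ((y−μ̂)/√μ̂)² / (n−k). With an OLRE the check marginalises
over it: a log-normal observation intercept with variance σ² implies
E[y] = μ·e^{σ²/2} and Var[y] = E[y] + E[y]²(e^{σ²}−1), and the ratio is
computed against that mean and variance. Conditioning on the OLRE modes
instead would over-shrink the residuals (ratios ≈ 0.3 on well-fitted
data) and say nothing about residual overdispersion. Note that on
negative-binomial data the ML log-normal OLRE variance slightly
over-matches the NB variance (confirmed against `glmer` on the same
draws), so a well-absorbed fit shows a ratio somewhat *below* 1 — the
check's contract is "no residual overdispersion", not "exactly 1".

**Per-term Wald F.** For the models with land use and intensity fitted
separately, each term gets F = (Lβ̂)ᵀ(LV̂Lᵀ)⁻¹(Lβ̂)/rank(L) with
denominator df n − p (recorded in the output). The exact ANOVA flavour
behind the originally reported F values is unstated, so those values are
not used as checks; the implementation is calibrated instead (type-I ≈ 5%
under planted-null simulation, part of the acceptance battery).

## 4. Percentage effects

1000 multivariate-normal draws of β (seeded; covariance eigen-floored at
zero against rounding), per-draw back-transform of class and baseline
linear predictors, ratio × 100, then median and 2.5/97.5 percentiles.
Back-transform rules, a genuinely open choice: log-link models use exp(η)
(so class-vs-baseline is exactly 100·exp(β_class)); ln(x+1)-scale gaussian
models use exp(η)−1, keeping percentages on the natural response scale —
the plain exp(η) ratio ships as a sensitivity option. Within-type
minimal-vs-intense contrasts are computed per draw and then summarised,
never as ratios of medians. Draws with a non-positive back-transformed
baseline are excluded and counted; more than 1% of them flags the
estimate unreliable. Stratified analyses (zone, order) express each class
against the primary-minimal prediction *within the same stratum* by
aligning per-stratum baseline rows. Gradient curves span the central 95%
of each stratum's sampled covariate values; the percentage-change-over-
range summary anchors at the low end of that span.

## 5. Validation battery

* **Continental jack-knife:** refit with each continent excluded; classes
  emptied by an exclusion drop out of that refit (logged); non-convergence
  is recorded, not fatal. Continent labels are an input column.
* **Moran's I:** per study, I = (n/ΣW)·(Σwᵢⱼeᵢeⱼ/Σeᵢ²) with inverse
  great-circle-distance (haversine, km) weights, zero diagonal,
  row-standardised; co-located pairs get weight 0 with a warning. p is a
  two-sided permutation test (999 permutations, seeded) — robust at the
  small per-study n where normal approximations are not. Studies with
  < 4 distinct coordinates are excluded from the percentage denominator;
  the original denominator definition is unstated, so the choice is
  logged. The implementation is pinned to a literal double-sum oracle at
  1e-12 in the tests.
* **Balanced resampling:** 1000 sites per zone (lowered with a warning if
  a zone is smaller), 100 reps by default, refitting
  intensity × zone and collecting interval widths per zone.
* **Forest-cover baselines:** primary-minimal sites split at cover ≥ 0.60
  (inclusive) vs ≤ 0.40, middle excluded; empty subsets skip the
  comparison with a warning.

## 6. The synthetic-data generator

What it emulates: nested study/block/site structure with log-normal study
(SD 0.5) and block (SD 0.3) intercepts; per-study species pools (30
species, log-normal abundance effects SD 0.8); negative-binomial counts
(size k = 1, i.e. genuine overdispersion for the OLRE machinery to earn
its keep); occupancy (presence) and abundance-given-presence planted
*separately* so richness and abundance effects can differ; effort drawn
per site in [0.5, 1] scaling expected counts (so the ingest adjustment has
something real to undo), with a missing-at-random option; ~1° study boxes
with uniform site coordinates (so per-study Moran's I is computable), 40%
of studies tropical; an optional spatially correlated residual field to
give the Moran screen something to find; a templated abstract corpus with
four positive cue types and negative cues, distractor plant binomials, and
a reference taxonomy with subfamily/tribe structure; smooth non-negative
covariate surfaces (constant + Gaussian bumps) on ESRI ASCII grids.

Default planted abundance effects follow the qualitative pattern the
design exists to detect — low/intermediate intensity beneficial, high
intensity harmful (urban-intense 0.60, pasture-intense 0.40, urban-minimal
1.55, …) — with occupancy effects at 1.0, so the expected total-abundance
ratio of a class to baseline equals the planted multiplier exactly and the
`TruthRecord` percentage is exact. The planted richness percentages are
occupancy ratios; realised richness also reflects zero-truncation of
counts, so richness truth is approximate by construction and the richness
tests are directional rather than exact.

What it does not emulate — and hence what passing tests do not show about
real data: realistic species-abundance distributions beyond log-normal
effects, phylogenetic signal, detection differences among taxa,
non-random placement of land uses in space, correlated study/block sizes,
or any real geography (continent labels are independent of coordinates).
Parameter recovery here demonstrates the *estimator chain* is unbiased and
calibrated under the stated generative model, not that the model is true
of any survey compilation.

The per-study block extent (1° box) is a placeholder: the spatial size of
a "block" is not defined by the source data model, and the value only
matters for the within-study distance scale of the Moran screen.

## 7. Problem sizes and seeds

The acceptance battery runs 100 seeded corpora for roster recovery, 100
replicate simulations of ≈ 1,500 sites each for planted-effect recovery
and for null calibration (each replicate: generate → ingest → metrics →
LMM fit → 1000-draw bootstrap), 200 synthetic studies for Moran type-I
control, and 1,000 random communities for the metric oracles. The
acceptance script uses 25 corpora and 40 replicates per arm. All
randomness flows from a master seed through per-stage SHA-256-derived
sub-seeds (`pipeline.stage_seed`), so adding a stage never perturbs
another stage's stream and every run is exactly reproducible.

## 8. Known limitations

* Random slopes, spatially explicit covariance, and zero-inflated
  negative-binomial abundance models are out of scope (the last is a
  deliberate non-goal; the gaussian ln(x+1) model is the main abundance
  estimator).
* The Poisson engine's Laplace approximation shares lme4's known weakness
  for OLRE models (per-observation random effects give the approximation
  its hardest case); variance components match `glmer`, but both are
  approximations to the true ML.
* Wald F with n − p denominator df is anti-conservative for few studies;
  with the default 25 studies the calibration test keeps it within the
  acceptance band, but users fitting handfuls of studies should prefer
  the bootstrap intervals.
* `filter_records` keeps a record if its genus is rosterable; records
  identified above genus level are not matched (the synthetic generator
  always writes genus).
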