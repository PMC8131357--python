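# pollidiv

Space-for-time analysis of land-use-intensity effects on pollinator
biodiversity, packaged as a tested, fully synthetic-data-capable pipeline.

## The problem

Global assessments of pollinator decline lean on local ecological survey
compilations (PREDICTS-style: sites nested in spatial blocks nested in
studies) crossed with a semi-automated literature judgement of *which*
surveyed taxa actually pollinate. The analysis chain is long — roster
construction from abstract evidence, site filtering, effort adjustment,
diversity metrics, mixed-effects models, a variance-covariance bootstrap of
percentage effects, and a battery of robustness checks — and each link has
conventions that matter. `pollidiv` implements the whole chain as a library
with a CLI, and ships a synthetic-data generator with *known ground truth*
so every stage is testable without downloading anything.

Intended users: macroecologists and biodiversity-informatics developers who
want to re-run, audit, or extend this class of land-use-intensity analysis.

## What it computes

For each site *s* (in block *b* in study *g*) the responses are species
richness S, Chao1 richness S + F₁(F₁−1)/(2(F₂+1)), effort-adjusted total
abundance A, and inverse Simpson diversity 1/Σpᵢ². Models are

* richness, Chao1: Poisson log-link GLMM,
  log μ = Xβ + u_study + u_block (+ u_site, an observation-level random
  intercept absorbing overdispersion);
* abundance, Simpson: gaussian LMM on ln(x+1).

The fixed design X is the combined land-use × intensity class (LUI, e.g.
`Urban_Intense`) against a primary-vegetation-minimal-use baseline, or
intensity × geographic zone / taxonomic order for the cropland analyses, or
log10(fertiliser rate + 1) gradients. Random structures are chosen by AIC;
any model whose AIC exceeds its intercept-only null is discarded. Effects
are reported as percentages of baseline: β is drawn 1000 times from
N(β̂, V̂), each draw's class and baseline predictors are back-transformed
(exp for log links, exp(η)−1 for ln(x+1) models) and ratioed, and the
median and 2.5th/97.5th percentiles summarise the draws.

Validation: continental jack-knife, per-study Moran's I on residuals
(inverse great-circle-distance weights, permutation p), balanced
tropical/non-tropical resampling, and forest-cover-stratified baselines.

The mixed-model engine is internal (exact profiled ML for gaussian,
Laplace-approximate ML for Poisson, random intercepts only); its agreement
with statsmodels `MixedLM` and lme4 `glmer` is part of the test suite.

## Worked example

```
$ pollidiv run-all --seed 4 --out demo --analysis global_lui
richness: excluded
chao1: excluded
abundance_ln1p: kept (lowest class Pasture_Intense: 37.0% of baseline)
simpson_ln1p: excluded
Moran screen abundance_ln1p: 0.00% of 25 studies significant
outputs in demo/ (manifest.json for bookkeeping)
```

Reading this: the default synthetic design plants multiplicative
*abundance* effects only (e.g. intensively used pasture at 40% of the
baseline's expected abundance, intense urban at 60%), so the total-abundance
model is the one that survives the AIC gate — the richness and Simpson
models are correctly judged uninformative against their nulls, and the
recovered low point (37.0% for `Pasture_Intense`, planted truth 40%) sits
inside its bootstrap interval. No study shows significant residual spatial
autocorrelation. `demo/` then contains the survey table, the compiled
pollinator roster, per-site metrics, per-model JSON summaries,
`effects_abundance_ln1p.csv` (class, median, lower, upper), and a manifest
with per-stage seeds and row counts.

The same stages are callable as a library (`pollidiv.simulate`, `.roster`,
`.ingest`, `.metrics`, `.models`, `.effects`, `.validation`,
`.pipeline`); see `docs/methods.md` for the statistical detail.

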