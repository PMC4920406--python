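# Methods

## Rewards per floral unit

**Nectar.** A sample is a 24 h standing crop (insects excluded) measured
either directly (microcapillary volume + Brix) or by flushing small flowers
with distilled water and reading the Brix of the solution. Sugar mass uses
s = 10·d·v·C mg with the empirical sucrose-solution density polynomial
d(C) = 0.0037921C + 0.0000178C² + 0.9988603 g/ml, valid for C ∈ [0, 85];
out-of-range readings are domain errors, never clamped. The flush protocol
treats the solution volume as the added water volume — the nectar volume
inside tiny flowers is negligible relative to a 20–50 μl flush; an explicit
`residual_nectar_ml` correction exists but defaults to 0. Brix is taken as
sucrose-equivalent (sucrose refractometer); no sugar-composition correction.
Accumulation windows other than 24 h are rescaled linearly. Species
summaries are means ± 1 SEM in μg/floral unit/24 h; the SEM is reported as
NaN for n = 1 rather than 0. Species whose samples are all zero are retained
with `zero_flagged=True`: flushing can fail to recover nectar from deep
florets, so an all-zero species is a possible false negative, not evidence
of zero secretion.

**Pollen.** Grains from a known number of floral units are suspended
(typically 1000 μl), an aliquot (typically 1 μl) counted on a
haemocytometer, and the count scaled to grains per floral unit. Grain volume
is the ellipsoid (4/3)π(A/2)(B/2)² from major/minor axes in μm; the species
mean is the mean of per-grain volumes (Jensen-consistent), not the volume at
mean axes. Unit conversion is exact: 1 μl = 10⁹ μm³. Floral units are single
flowers except for Asteraceae, quantified per capitulum
(`floral_unit_kind`). Daily rates divide total volume per unit by floral
longevity.

**Longevity.** The two-visit census estimator L = (2a+(b−c))/((b−c)·d) is
implemented as printed (a = open units at visit 1; b, c = newly open /
newly closed at visit 2; d = days between visits). Two degeneracies are
surfaced rather than smoothed over: b = c (stationary census) makes the
printed form undefined, and b < c can make it negative; both raise typed
errors. A turnover variant (2a+(b−c))/((b+c)·d) is available via
`method="turnover"`; for a stationary population observed at d = 1 day (the
field protocol) it recovers the true mean lifetime, which the birth–death
simulation in the test suite verifies. For d ≠ 1 under stationarity the
turnover form scales as L/d², so census intervals other than 24 h should be
used only with growing/shrinking populations and the printed form — a
limitation of this estimator family, documented here because the package
deliberately does not guess which form the original protocol intended.

## Budgets per meadow

Surveys are long-format quadrat counts (site, treatment, round, quadrat,
species, count per 1 m²). A quadrat roster makes implicit zeros countable;
species absent from a quadrat count as zero there. Per-m²/day resource is
Σ_species density × reward/unit/day; meadow totals multiply by area
(default 300 m²). The 95% CI treats the per-quadrat total resource (counts ×
rewards summed within a quadrat) as the sampling unit: mean ± 1.96·SE over
quadrats. This propagates between-quadrat count variation only; reward SEMs
are deliberately not propagated. Species with no reward profile are excluded
from sums — never silently: a warning is raised and a `coverage` statistic
(fraction of counted units belonging to profiled species) is attached to
every estimate so the analyst can check the ">99% of floral units measured"
condition.

Calibration of this CI was measured by simulation (see
`synth.simulate_ci_coverage`): over 500 site-rounds at the default study
conditions, coverage is ~0.88–0.91, not the nominal 0.95. Two causes: the
normal approximation at n = 20 quadrats is optimistic for strongly skewed
negative-binomial totals, and rare species with large per-unit rewards are
often counted in none of the 20 quadrats, so their true contribution lies
outside a CI built from observed counts. The interval should therefore be
read as an order-of-magnitude error band for heavy-tailed communities.

**Sampling effort.** `subsample_simulation` draws quadrat subsets without
replacement (vectorised via random-key argsort) and reports the mean and
across-replicate variance of the subset-mean estimate per subset size — the
basis for choosing a 20-quadrat scheme. `scheme_comparison` computes the
paired 7-edge-quadrat vs all-quadrat estimates with signed percent
differences. Edge/internal position is metadata; both schemes weight
quadrats equally.

**Season totals.** `seasonal_integral` integrates a daily-rate series over
survey days, either by the trapezoid rule on observed points or by fitting a
Gaussian-in-log-space bloom curve (a concave quadratic in log rate, positive
points only) and returning its closed-form area exp(a₀ − a₁²/4a₂)·√(π/−a₂);
if the fitted quadratic has no interior peak the empirical trapezoid is
returned instead.

## Predictive models

**Pollen from morphology.** OLS of log_e(pollen per floral unit, μl) on
1/stamen-number plus anther size-class indicators with 'large' as the
reference class ('tiny' is reserved for Asteraceae; class boundaries ~1.25
and 2.25 mm³ are available in a helper but classes are normally supplied as
data). The published coefficient vector (2.34, −8.98, −3.28, −5.59, −4.49)
ships as `PollenMorphologyModel.published()`. Note the published 'small'
coefficient is more negative than 'tiny', inverting the nominal size
ordering — the model is applied exactly as fitted, and the prediction-order
test pins this behaviour. Absent classes are dropped from the design and
reported. Validation regresses measured on predicted values on the log
scale (the natural scale of the fit); the choice of scale is a documented
convention. Box–Cox transform selection maximises the profile
log-likelihood on λ ∈ [−3, 3] (scipy's `boxcox_llf` under bounded scalar
minimisation) with LR tests against λ = 0 and λ = 1; for low-CV data λ is
weakly identified — any power is near-linear over a narrow positive range —
so the LR decisions, not the point estimate, are the meaningful output
there. No nectar-from-morphology model is provided: no useful predictive
relationship exists for nectar, and offering one would invite misuse.

**Resource from counts.** OLS on the log_e–log_e scale of per-m² resource vs
floral-unit count across surveys; non-positive pairs are excluded before the
transform (count reported). Predictions back-transform by exp without a
smearing correction, matching the convention of the published fits
(slopes 0.721 nectar, 0.748 pollen, available as
`CountResourceModel.published`). Sublinear slopes arise when surveys with
the highest counts are dominated by species with below-average per-unit
rewards.

## The synthetic study

The generator provides ground truth for every stage; a single integer seed
feeds independent child streams (pool, site effects, assays, surveys), so
identical configs are byte-identical. Defaults, with rationale:

- **60 species**, 30% weeds, 35% Asteraceae — the scale of a two-mix urban
  meadow flora.
- **Abundance**: lognormal base densities, σ = 2.5 around a median of
  3 units/m², capped only by the count distribution — a handful of species
  reach 10²–10⁴ units/m² in single quadrats while many sit below 0.1/m².
- **Rewards**: log-uniform within the observed envelopes (nectar
  0.6–2921 μg/unit/24 h; pollen 0.0004–15.9 μl/unit; longevity 1–14.8 d,
  quantised to 0.25 d so integer census counts reproduce truth exactly).
  Rewards share a Gaussian copula with log abundance (ρ = −0.6): the
  superabundant species tend to be tiny-flowered and poorly rewarding, but
  the tradeoff is not deterministic — some abundant species are highly
  rewarding, as in real meadow floras.
- **Phenology**: Gaussian bloom curves per group (perennial peak round 4 ≈
  early August, annual round 5.5 ≈ late August–September, weeds round 1.5)
  with species-level peak jitter (sd 1.5 rounds). Weeds grow in sown
  meadows at 10% of their seed-bank potential (large weeds are removed in
  managed meadows) and are the only flora of the mown control, at 1% density.
- **Counts**: negative binomial (dispersion 1.5) around truth mean density;
  the Poisson limit as dispersion → ∞ is tested.
- **Assays**: replicate numbers mimic field practice (nectar 3–22, pollen
  2–22 per species); multiplicative lognormal noise with mean 1 (cv 0.3), so
  the zero-noise configuration recovers truth exactly. Pollen aliquot counts
  are kept real-valued (expected counts) for the same reason. Longevity
  censuses are integer counts constructed to invert the printed estimator at
  d = 1 (b − c = 8, a = 4(L−1)).
- **Morphology**: stamen numbers and anther classes drawn so measured pollen
  follows the published coefficient vector with σ = 0.3 log-scale noise;
  refitting recovers each planted coefficient within 2 SE.

What the generator does **not** emulate: within-meadow spatial structure
(quadrats are exchangeable draws), weather and drought shocks, between-city
reward variation, visitation/depletion dynamics, and any correlation between
nectar and pollen rewards beyond their shared abundance coupling. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated sampling model, not robustness to spatial autocorrelation or
environmental covariates.

Two ensemble behaviours deserve note. First, the perennial-before-annual
peak ordering holds for the ensemble mean series; a single draw can invert
it when one late-jittered perennial dominates, so the test averages over
seeds. Second, at the default moderate reward–abundance tradeoff the pooled
count→resource slope sits near but not always below 1 (seasonal bloom scales
all species together, an elasticity-1 axis); the sublinearity test therefore
uses an explicit strong-tradeoff community (ρ = −0.9, σ = 3.0) to
demonstrate the mechanism.

## Pipeline and reporting

`run_pipeline` is a pure function of (inputs, config, seed): synthetic or
CSV inputs → species profiles → per-site-round budgets → contribution
stacks → model fits → bee equivalents → per-treatment summary (mean,
median, quartiles; empty treatments give explicit NA). Warnings (coverage
< 0.99, rejected longevity observations, unmatched species) are collected
into the run log, never swallowed; any stage failure aborts with the stage
name. A site exclusion list handles failed meadows as input metadata.

## Problem sizes

Test and validation runs use one synthetic city (2 sites × 4 treatments ×
6 rounds, 20 quadrats) for end-to-end checks, 99 quadrats × 10 000
replicates for the sampling-effort simulation, 500 site-rounds for CI
calibration, and n = 59 species for morphology recovery — matching the
scale of the original survey design while keeping the whole suite and the
acceptance script in the seconds-to-minutes range on one CPU.
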