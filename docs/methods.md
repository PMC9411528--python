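# Methods

## The model

The quantity of interest is the exponent `k` of the predator–prey power law
`y = c·x^k`, fitted on log10 scales as `log10 y = log10 c + k·log10 x`.
Two levels of organisation are analysed:

* **Within webs** — one observation per predator: its standing biomass `y`
  against the total biomass of its prey `x`. Because prey are shared, each
  prey's biomass is divided by its vulnerability (number of consumer nodes
  feeding on it, all consumers counted regardless of their own biomass)
  before summing over a predator's diet; interaction strengths are treated
  as equal because link weights are generally unavailable for community
  data of this kind. An unadjusted variant (`adjust_vulnerability=False`)
  is exposed for sensitivity analysis.
* **Across webs** — one observation per web: the summed biomass of all
  qualifying predators against the summed biomass of the union of their
  prey, each prey counted once at full biomass. A node that is both
  predator and prey contributes to both totals; a vulnerability-shared
  prey total is available behind `share_prey_across`.

Node biomass is numerical abundance (individuals m⁻²) × mean individual
body mass (g dry weight), so all biomasses are g dry weight m⁻².

### Trophic metrics

Prey-averaged trophic level solves `TL = 1 + D·TL` exactly, with `D` the
row-stochastic diet matrix (equal weights `1/generality` across each
consumer's prey, zero rows for basal resources). The linear solve handles
feeding loops; the system is singular exactly when a loop has no path to a
basal resource, which raises an error naming the offending strongly
connected component. A fixed-point iteration from `TL = 1` is kept as an
independent cross-check. Cannibalistic self-links are stored on the web
but excluded from every metric and from prey-biomass sums, since the TL
recursion is otherwise ill-defined.

Omnivory is the variance of a consumer's prey trophic levels. The
*population* variance (denominator = number of prey) is used — the prey
set is the complete set of links, not a sample — and a consumer with one
prey gets 0. PPmR is log10(predator body mass / unweighted arithmetic mean
of prey body masses). Both conventions are configuration points in
principle; the defaults above are the package's reading of "variance" and
"mean" for diet sets.

### Filters

Predators are nodes with prey-averaged trophic level strictly above
`tl_cutoff` (default 2.5; 3.0 is the usual sensitivity setting); this
restricts the analysis to predators feeding on animal prey, since basal
resource biomass is typically not measured. Nodes flagged as coarse
taxonomic aggregates (e.g. "zooplankton") are excluded from the within-web
records but retained in across-web totals. Webs are kept only with at
least `min_predators = 5` qualifying records and at least
`min_x_range_decades = 1` of spread in the per-predator prey-biomass
covariate — the spread of the *regressor*, since that is what limits slope
estimation (raw node biomasses would overstate the usable range). Records
with non-positive biomass on either axis are dropped with a log entry
before the web filter, which is idempotent.

## Estimation

OLS (type-1) regression throughout; no SMA/RMA variants.

**Within-web LME.** Records are predators nested in webs, so slope and
intercept get per-web random deviations. Model selection is top-down in
two stages:

1. With the full fixed structure (`log10 x` × ecosystem type), the random
   structure is chosen by REML AIC among {correlated random
   slope+intercept, uncorrelated, intercept-only}. A structure whose
   fitted random-effects covariance is singular (smallest eigenvalue
   < 1e-8 × trace) is discarded with a warning in favour of the next
   simpler one; if none is estimable the model collapses to OLS.
2. Under the selected structure, ML likelihood-ratio tests drop the
   ecosystem × slope interaction and then the ecosystem main effect at
   α = 0.05. The selected model is refitted by REML and reports `k̄` with
   a 95% Wald CI (profile CIs were considered and not implemented; Wald
   intervals are standard for fixed effects at these group counts).

Per-ecosystem slopes and their CIs come from the full interaction model
(REML), resolved from the treatment coding to absolute slopes (alphabetical
reference level). R² is reported in the marginal and conditional
(variance-partitioning) flavours; any before/after comparison should use
the same flavour. With a single web the fit degenerates to plain OLS, and
exactly collinear (noise-free) data short-circuit to the exact line, since
a zero-residual mixed model is numerically meaningless.

Fitting uses quasi-Newton optimisation of the profiled REML/ML deviance
with OLS starting values (statsmodels `MixedLM`), walking through l-bfgs →
bfgs → cg → powell until convergence; a model that still fails raises a
typed error carrying the optimizer state.

**Trait-augmented LME.** PPmR and omnivory enter as fixed effects, each
interacted with ecosystem type, on top of the selected within-web model.
Candidate predictors are screened: constant columns are dropped, and of
any pair with |pairwise r| > 0.7 the later one is dropped (the biomass
covariate always stays). Term tests are F tests whose denominator degrees
of freedom use Satterthwaite's approximation: the variance of a contrast
`L'β̂` is differentiated numerically with respect to the variance
components, whose sampling covariance is the inverse observed information
of a direct REML log-likelihood (implemented in `_LMMProfile`,
independently of the fitting route); multi-df terms combine
per-eigenvector 1-df approximations. When the information matrix is not
positive definite the test falls back to a likelihood-ratio χ² with a
logged notice. Partial residuals (marginal residual + the trait's own
fixed-effect contribution) are returned for plotting.

**Across-web ANCOVA.** OLS of log10 total predator biomass on log10 total
prey biomass × ecosystem type; an F test compares the common-slope null
against separate slopes. `k̄` is the mean of the per-ecosystem slopes; the
reported CI is from the common-slope model. The same machinery fits the
prey-size diagnostic (log10 mean prey body mass vs log10 total prey
biomass; a slope near 0 means biomass gradients are density-driven).
Outlier webs for that diagnostic are a data annotation supplied by the
user, not computed. Mean prey mass is unweighted by default
(`weight_prey_mass_by_abundance` switches). Per-species fits regress one
predator taxon's biomass on its available prey biomass across the ≥ 5 webs
where it occurs.

## The synthetic generator

The generator emulates community datasets of the kind the pipeline
targets: multiple webs per ecosystem type, lognormal-ish body masses and
abundances, omnivorous link structure, and a log-log-linear predator–prey
relation with per-web random slope/intercept deviations and lognormal
residual noise.

Topology is layered and niche-ordered: basal resources in layer 0,
consumers split evenly over `n_layers − 1 = 3` upper layers. Each consumer
draws `1 + Poisson` prey from strictly lower layers — one anchored in the
layer immediately below (guaranteeing ≥ 3 trophic layers and, with one
node per layer, a forced chain) and the rest weighted 2 : 1 in favour of
that layer, which produces strong omnivory and non-integer trophic levels.
The Poisson mean targets a directed connectance (links/S²) of 0.10, the
canonical food-web value. An optional flag injects upward links to create
feeding cycles for stress-testing the trophic-level solver; biomass
assignment requires an acyclic skeleton.

Biomass is assigned bottom-up in topological order: basal biomass is
log-uniform over 4 decades around a per-web community offset (log-uniform
over 3 decades — datasets of this kind span communities from sparse to
rich, and the across-web regression needs that gradient); each consumer's
biomass is then `10^(c_i + traits + ε) · x^(k_i)` with `x` its
vulnerability-adjusted available prey biomass, `(k_i, c_i)` the web's
parameters drawn from a correlated bivariate normal around
`(k̄, c̄) = (0.75, −0.5)` with SDs `(σ_k, σ_c) = (0.05, 0.3)`, correlation
0.3, and `ε ~ N(0, σ_res = 0.3)` in log10 units. Body mass climbs 2
decades per trophic level (a typical size jump between levels) with 0.6
decades of lognormal scatter — enough within-level size variation that
PPmR and omnivory are not structurally collinear, as they would be if mass
were a deterministic function of trophic level. Abundance is biomass /
mass, so re-ingesting the written tables reproduces the generating
covariate exactly and parameter recovery is a sharp test. Trait
coefficients default to 0 so trait tests exhibit null behaviour unless an
effect is injected. Each web has its own RNG substream spawned by counter
from the dataset seed: identical config + seed is byte-reproducible and
webs are independent of generation order.

**What the generator does not emulate**, and hence what passing tests do
not establish about field data: taxonomy, sampling error in abundance and
body mass (the generator's biomasses are exact), link errors
(false/missing feeding links), interaction-strength variation, detrital
and basal-resource dynamics, and environmental covariates. One structural
feature deserves note: because biomass cascades upward, a web's intercept
deviation `ε_c,i` also shifts the prey-biomass covariate of its top
predators, so the random effects are not perfectly independent of the
regressor. Per-web OLS slopes are exactly unbiased (the conditional
relation holds record by record); the LME's mean-slope estimate carries a
small (~+0.01 at these defaults) finite-sample bias from the between-web
information, which the recovery tests bound. Real data share this
endogeneity whenever prey biomass is itself generated by the same
community processes.

## Problem sizes and numerical choices

* Recovery simulations use 30 webs × ~15 qualifying predators per web
  (web size 30, 6 basal) and 50 Monte-Carlo replicates; type-I and
  coverage-style checks use 10–20 seeded replicates at 12–30 webs. These
  sizes put Monte-Carlo error comfortably below the effects being checked.
* Trophic-level solves: `numpy.linalg.solve` with a residual check
  (> 1e-6 triggers SCC diagnosis); fixed-point iteration runs to a step
  tolerance of 1e-12.
* LME convergence: statsmodels defaults (relative deviance tolerance
  ~1e-8) with the optimizer ladder above; Satterthwaite finite differences
  use central steps of 1e-4·(|θ|+1e-3).
* Noise-free detection: pooled-OLS residual SD < 1e-10.
* CSV round trips write 17 significant digits and parse with
  `float_precision="round_trip"`, so `read(write(W)) == W` bit-exactly.

## Limitations

* Satterthwaite df rely on numerically differentiated information; at very
  small group counts (< ~5 webs) the fallback LRT path is common.
* The across-web exponent is an emergent property of the generator (totals
  of a within-web power law), not an injected parameter, so across-web
  recovery checks are interval-based rather than exact.
* The `fit_species_across_webs` helper assumes taxon names are comparable
  across webs; no synonym resolution is attempted.
* No plotting: fit objects and tidy CSVs are designed to drop into any
  plotting layer.
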