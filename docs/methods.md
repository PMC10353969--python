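# Methods

This note documents the models, the synthetic data generator, the
numerical choices, and the limits of what the test suite demonstrates.

## The two outcomes

The package analyses genealogical birthplace records from a two-region
study design: one interviewed proband per family reports the birthplaces
of seven people (self, mother, father, four grandparents). From these,
two outcome sets are constructed.

**Migration dyads.** Each family contributes up to six child–parent
dyads (proband–mother, proband–father, and each parent against their own
two parents). The *mover* is the parent or grandparent of the dyad — the
person who did or did not move between their own birth and the birth of
their child — and the dyad's distance is the great-circle distance
between the two birthplaces. The child-side birthplace anchors the
dyad's birthplace index b(i), because it is the side that is nearly
always known exactly. Dyads fall into four states:

- *observed*: both birthplaces exact; distance d known; migrated ⇔ d > 0;
- *interval-censored*: the mover's birthplace is known only as a region
  different from the anchor's; migration certainly occurred and d lies
  between the nearest and farthest points of that region from the anchor;
- *latent-status censored*: the mover's region contains the anchor
  place; the distance is at most the farthest point of the region, but
  whether migration occurred at all is unknown (the mover may have been
  born exactly at the anchor place). The likelihood marginalizes over
  the indicator rather than assuming migration occurred; a
  ``same_region_assume_migrated`` switch instead treats these dyads as
  known migrants censored to (0, d_max];
- *missing*: an endpoint is wholly unknown; excluded from fitting.

**Residence types.** Each family contributes up to three parent couples.
A couple's postmarital residence type compares the child's birthplace to
both parents' at gazetteer place resolution: equilocal (same as both),
matrilocal (mother only), patrilocal (father only), neolocal (neither),
or missing when a comparison is undecidable. A region-only birthplace in
a *different* region than an exact one is decidably different; in the
same region it is undecidable and the couple is missing. These are
birthplace-based constructs, not household records, and deliberately
differ from the classical residence definitions.

## The hurdle migration model

Distance d ≥ 0 is semicontinuous: a point mass at zero (no migration)
plus a log-normal density for movers,

    h(d) = 1 − π          (d = 0)
         = π g(d; μ, σ_E) (d > 0)

with, for dyad i in family l(i) anchored at birthplace b(i),

    logit(π_i) = x_i'β + S_l(i) + T_b(i)
    log d_i    = x_i'γ + U_l(i) + V_b(i) + E_i,  E_i ~ N(0, σ_E²)

Censored dyads contribute Φ-differences of the log-normal CDF; the
latent-status state contributes (1 − π) + π Φ((log d_max − μ)/σ_E).

Covariates (both sub-models share x): intercept; the proband's birth
year, centred at the sample median and scaled to decades (a secular-trend
adjustment; the coefficient is per decade — a ``birth_year_source``
switch substitutes the mover's own recorded birth year, or the couple's
child's in the residence model, where available); and the full factorial of
the mover's sex × generation (parent/grandparent) × region with all
interactions. Reference levels: female, grandparent, and the
alphabetically first region (cederberg). Variants append either
settlement-size dummies of the mover's own birthplace (town/farm/unknown
vs. city; censored movers are coded unknown) or two ancestry covariates.

Ancestry enters as additive log-ratios of a three-component proportion
vector (Khoe-San, West/Central African, Eurasian), floored at ε = 10⁻³
and renormalized so degenerate simplices stay finite. Log-ratios were
chosen over raw ratios because raw ratios are unbounded and asymmetric;
the proband's ancestry proxies the whole family's.

Priors follow a regularizing hierarchical scheme: β ~ MVN(0, Σ_β) and
γ ~ MVN((log 100, 0, …), Σ_γ) — the log 100 baseline makes 100 km the
central prior distance — where each covariance splits into a scale
vector with half-Cauchy(0,1) priors and an LKJ(2) correlation matrix.
S, T, U, V are zero-mean Gaussians with half-Cauchy(0,1) scales; σ_E is
half-Cauchy(0,1). Group intercepts are sampled non-centred (raw
standard normals scaled inside the model), which is the appropriate
parameterization for the many small families in these designs.

## The multi-logit residence model

For couple c with family l(c) and male/female birthplaces b_m(c),
b_f(c), the log-odds of type r ∈ {neolocal, matrilocal, patrilocal}
relative to equilocal (the reference, being the most common type) are

    log(π_rc / π_ec) = x_c'δ_r + W_{r,l(c)} + Y_{r,b_m(c)} + Z_{r,b_f(c)}

Covariates: intercept, proband birth year (decades, centred), generation,
region, generation × region; variants append settlement size of the
couple's postmarital settlement — operationalized as the child's
birthplace, since every construct here is birthplace-based — or the
ancestry log-ratios. The three δ_r are concatenated under one joint
hierarchical MVN prior (half-Cauchy scales, LKJ(2) correlation), so
covariate effects may correlate across residence types; W, Y and Z
triples each get their own 3×3 hierarchical covariance and are sampled
non-centred. The choice of reference category is algebraically
immaterial; the test suite verifies that MAP fits under an equilocal
vs. neolocal reference (with congruently transformed fixed prior
covariances) give identical fitted probabilities.

## Geodesy and censoring bounds

Distances are Haversine great-circle distances on a sphere of radius
6378.137 km (the WGS-84 equatorial radius, matching the convention of
the common R distance tooling); the radius is a configurable constant.
Region polygons are rings of (lat, lon) vertices. Point-to-region
minimum/maximum distances are evaluated on the boundary after densifying
edges to ≤ 1 km segments; for sub-degree regions the densification error
(< 10⁻⁴ km) is far below the kilometre precision of the data. A point
inside or on the region has minimum distance 0. Place identity (for
"same birthplace") is by gazetteer place id, not zero distance, since
two named places could share coordinates at gazetteer precision.

## Inference

The log-posteriors of both models are differentiable over an
unconstrained parameter vector (scales enter as logs with Jacobians;
correlation matrices through tanh-transformed canonical partial
correlations of their Cholesky factors). Gradients are analytic and
verified against central finite differences at 10⁻⁵ relative tolerance.

Sampling uses a no-U-turn sampler (dynamic HMC with slice-based
trajectory selection), dual-averaging step-size adaptation towards a
0.9 acceptance target, and windowed diagonal mass-matrix adaptation.
Chains initialize at a *partial* posterior mode (L-BFGS over location
parameters with covariance hyperparameters and log-scales frozen at
moderate values) plus jitter; the joint mode of a hierarchical model
collapses into the funnel tip (scales to zero) and is useless as a
starting point.  The initial diagonal metric comes from
finite-difference curvature of the analytic gradient at that point.
Simulation studies that refit the same model structure repeatedly
warm-start the adapted metric and step size from the first fit, with a
shortened warmup thereafter — adaptation is tuning, not inference, so
this changes no posterior.  The hurdle model's log-posterior gradient
additionally has a numba-compiled kernel, pinned to the numpy reference
implementation at 1e-10 in the tests and used automatically when numba
is importable.

The migration model's coefficient blocks can be sampled centered
(default; appropriate when the likelihood pins the coefficients) or
non-centered through the prior Cholesky (appropriate for small,
prior-dominated datasets, where the centered form is a funnel); the two
describe the identical posterior. The sampler backend sits behind a minimal
contract — asymptotically correct draws from the supplied log-density —
and is validated on closed-form conjugate posteriors. Convergence is
summarized by split R-hat and bulk/tail effective sample sizes; runs
with max split R-hat above 1.01 warn rather than fail. Divergent
trajectories are counted and reported per chain.

Model comparison uses PSIS-LOO expected log predictive density computed
from the pointwise log-likelihood matrix (draws × observations), with
Pareto-smoothed importance weights; the smoothing replaces the largest
min(0.2 S, 3√S) raw ratios by expected order statistics of a
generalized Pareto fit to the tail. Pairwise elpd differences carry the
paired SE √(n · var(elpd_iᴬ − elpd_iᴮ)). The suite validates PSIS-LOO
against exact leave-one-out refits on a 50-observation dataset.

For posterior displays by demographic cell (region × generation × sex),
draws are marginalized over birthplace intercepts using the observed
relative frequencies of birthplaces within each cell as weights, with
family intercepts at their central value 0 and the birth-year covariate
at the reference (median) year; the reported quantities are the
cell-level odds of migration and median migration distance per draw.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
exercised. Defaults: two disjoint convex regions around realistic
south-western African coordinates; 100 and 75 birthplaces in the two
regions — the realistic density of named towns and farmsteads for rural
interview cohorts of this size, and important because region, a
place-level covariate, is identified only through the birthplace
intercepts — with a settlement mix of 7% city / 40% town / 45% farm /
8% unknown; 150 families per region; proband birth years ~ N(1957, 12²),
a mid-twentieth-century median typical of such cohorts; and true effects
producing realistic descriptive scales (roughly 45–50% migrants among
complete cases; median mover distance tens of km; region and generation
log-odds effects of 0.5; birth-year trends of +0.15 per decade on the
log-odds; σ_S = σ_U = 0.3, σ_T = 1.0, σ_V = 0.5, σ_E = 1.0).

Migration-driven generation walks each dyad forward through the true
hurdle model: Bernoulli migration on the dyad's log-odds, a log-normal
distance draw for movers, then assignment of the mover's birthplace to
the gazetteer place whose distance from the anchor is closest to the
draw. Distances are thereby discretized to the place grid, which adds
assignment noise to the continuous part (σ_E and γ recover with slight
attenuation) but leaves the binary part exactly model-distributed. When
settlement-size effects are configured, the mover's own (to-be-assigned)
birthplace influences its probability, so the generator switches to an
exact discrete conditional over {stay} ∪ {move to p} with weights
(1 − π(s_anchor)) and π(s_p)·K(d(a,p)), K a normalized log-normal kernel.

Residence-driven generation is type-first within the feasible set:
couples form with an exogamy knob (probability the partners' birthplaces
differ), the true multi-logit gives type probabilities renormalized over
the feasible types (equilocality requires a shared couple birthplace;
matrilocality/patrilocality require distinct ones), and the child's
birthplace is then assigned so the classifier reproduces the drawn type
exactly — verified internally on every dataset. Grandparent couples are
drawn before the parent couple so each parent's birthplace is consistent
between the couple they belong to and the couple they produced.
Closed-form expected type frequencies under this scheme are the
feasibility-renormalized softmax, mixed over the endogamy probability;
tests use that closed form, not the unrestricted softmax.

The observation process censors grandparent birthplaces to region-only
knowledge (default rate 0.25), deletes non-proband birthplaces entirely
(default rate 0.12), and can make grandparent missingness more likely
behind a migrant parent via an odds multiplier, emulating informants
knowing less about forebears of parents who moved away. The latent
truth record is kept separately and never altered by degradation; every
censoring interval provably brackets the true simulated distance.

What the generator does not emulate: marriage-market structure,
fertility/mortality, migration kernels with spatial direction (distance
only), informant recall correlated across roles, or geocoding ambiguity.
Passing tests therefore demonstrate correctness of the estimation
machinery under the stated generative assumptions, not robustness to
real-data pathologies beyond the censoring/missingness forms modelled.

## Problem sizes and run configurations

Test and acceptance runs use desk-scale configurations chosen as the
package's own defaults for simulation studies: recovery experiments use
20 replicates of 300 families (gazetteers of 100 + 75 places, the
generator's defaults) fitted with single chains of
300 warmup / 300 kept draws after partial-mode initialization,
warm-starting the metric across replicates; model-selection studies use
10–20 replicates of 40–60 families with chains of 250/250;
sampler-contract checks use 4 chains of 400/500 on ~200 outcomes with
the non-centered coefficient blocks; the PSIS-LOO versus exact-LOO
comparison uses 50 observations spread over 17 families (dyads whose
family or birthplace appears fewer than three times are excluded — a
deleted singleton leaves its group intercept data-free and makes the
point pathologically influential for any LOO method) and 51 warm-started
single-chain refits of 1000 kept draws. The full-study prescription
(4 chains × 6500 warmup / 1500 kept) remains the default of `FitConfig`
for analysis use.

## Known limitations

- Posterior means of weakly identified fixed effects shrink towards
  zero under the hierarchical coefficient prior; recovery experiments
  measure this as small negative bias, which is a property of the model,
  not a defect of the sampler.
- The nearest-in-distance place assignment attenuates σ_E slightly at
  coarse gazetteer density.
- Couple feasibility renormalization means observed type frequencies are
  not the unrestricted softmax; the fitted model ignores feasibility, so
  its intercepts absorb the renormalization on synthetic data.
- Hierarchical covariance hyperparameters (scales and correlations of
  Σ_β, Σ_γ, Σ_δ) are weakly identified at desk scale; their posteriors
  are prior-dominated and occasionally produce divergent transitions at
  short warmup lengths.
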