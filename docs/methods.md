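# Methods

This note documents the statistical model, the synthetic-data design, and
the numerical choices behind `spatqol`.

## Scientific setting

Patient-reported quality of life (QoL) after radical prostatectomy varies
geographically. The motivating setting is a state-wide clinical registry:
~5,200 men operated over seven calendar years, each completing the
EPIC-26 instrument twelve months after surgery, resident in one of ~80
local government areas (LGAs). The analysis asks (i) which individual-
and area-level factors are associated with poor QoL, (ii) how poor QoL
varies over space and time, and (iii) how sensitive the answers are to
the choice of spatial neighbourhood definition.

## Outcome derivation

EPIC-26 yields five domain scores on 0–100 (urinary incontinence,
urinary irritative/obstructive, bowel, sexual, hormonal; higher =
better). Because domain scores are heavily skewed, each domain is
categorised into cohort-empirical quartiles coded 1 (worst) to 4 (best);
the five codes are summed into a composite on 5–20; and a patient is
labelled *poor QoL* when the composite falls strictly below the cohort
median composite (the median itself is "good").

Numerical conventions (the source procedure leaves them open):

- Quartile cut points are empirical 25/50/75th percentiles with linear
  interpolation of order statistics, computed over the pooled cohort
  (not within year). Ties at a cut point go to the lower bin
  (`value <= Q1 -> 1`), making the map deterministic and monotone.
- The median split uses the standard midpoint empirical median; with the
  strict `<` comparison, "median and above" is good under any
  convention.
- Patients missing any domain score are excluded from scoring and listed
  in an exclusion report; no imputation.

`derive_outcomes` can also score a table against *frozen* thresholds
(cuts + median from a reference cohort), which is how sub-cohorts are
scored consistently.

## Spatial weight matrices

Two binary, symmetric, zero-diagonal constructions over the areal units:

- **Queen contiguity** — areas are neighbours if their polygons share at
  least one boundary vertex. Vertices are snapped to a 1e-9 tolerance
  grid before comparison, so exact toy lattices and slightly inexact
  real coordinates behave identically.
- **Distance band** — areas are neighbours if their centroids lie within
  a band `d` (planar Euclidean, km). `min_connecting_band` returns the
  smallest band leaving no isolated area, max_j min_{k≠j} d(j,k) — the
  selection rule behind the motivating study's 131 km band.

Weights are unstandardised 0/1; normalisation happens inside the CAR
prior through the neighbour-count divisor. Isolated areas are permitted
in a matrix (with a warning) but rejected by the model fitter unless
overridden, since an island's spatial effect is informed only by its
prior. GAL files (GeoDa dialect) and GeoJSON polygons are the exchange
formats.

## The model

For patient *i* in area *j(i)* with surgery year *t_i* (centred at the
midpoint of the year range, so 2015–2021 gives −3..3; centring reduces
t/t² collinearity):

    y_i ~ Bernoulli(p_i)
    logit p_i = α + x_i'β + δ₁ t_i + δ₂ t_i² + u_{j(i)} + v_{j(i)}

`x_i` one-hot encodes categorical covariates against declared reference
levels (age group ≤55, NCCN low risk, PSA ≤10, private institution,
"accessible" remoteness). Area-level covariates (IRSD quartile,
remoteness) enter as fixed-effect dummies attached to each patient. The
area effect follows the Besag–York–Mollié decomposition:

- **u** — intrinsic CAR (ICAR): improper prior with kernel
  ((J−c)/2)·log τ_u − (τ_u/2)·Σ_{j<k} w_jk (u_j − u_k)², constrained to
  sum to zero (c = number of graph components);
- **v** — exchangeable heterogeneity, v_j ~ N(0, 1/τ_v).

Priors: every fixed effect (including α, δ₁, δ₂) gets Normal(0,
precision 0.725). That precision is the value giving the odds ratio a
95% central prior interval of (0.1, 10): (z_{0.975}/ln 10)² ≈ 0.7246
(`prior_precision_for_or_interval` recomputes it). The precisions get
Gamma(0.5, 0.0005) hyperpriors, the classic BUGS convention for BYM
models; both are user-overridable.

## Sampler

A bespoke Metropolis-within-Gibbs sampler:

- **Fixed effects** — scalar Gaussian random-walk updates per
  coefficient with incremental linear-predictor maintenance (a proposal
  only touches patients in that column's support). Step sizes adapt by
  Robbins–Monro (γ_t = t^−0.6, target acceptance 0.35, comfortably in
  the 20–50% band) during burn-in only, so the post-burn-in kernel is a
  fixed, valid Metropolis kernel.
- **u** — single-site random-walk updates combining the area's
  likelihood contribution with the ICAR pairwise kernel. Updates are
  executed by greedy graph colour class: areas in a class share no edge,
  so their full conditionals are mutually independent and a class can be
  updated in one vectorised step (chromatic single-site Metropolis; same
  stationary distribution as a sequential sweep). After each sweep u is
  recentred to sum zero with the mean absorbed into α, leaving the
  likelihood invariant — the standard implementation of the ICAR
  sum-to-zero constraint.
- **v** — single-site updates for all areas simultaneously (iid prior,
  no cross-area coupling).
- **Shift moves** — a design column that is constant within areas (the
  intercept, and area-level covariates such as remoteness) is confounded
  with v: adding δ to the coefficient and subtracting δ from the v_j of
  the affected areas leaves every linear predictor unchanged. Single-site
  updates mix that direction extremely slowly, so for each such block the
  sampler adds an η-invariant joint proposal (β → β+δ, v_j → v_j−δ on the
  block's areas) whose acceptance ratio involves only the Normal priors —
  an ancillarity-style interweaving move that costs no likelihood
  evaluation and is what keeps area-level coefficients (and their
  credible intervals) honest at registry-like area counts.
- **τ_u, τ_v** — conjugate Gibbs draws: τ_u ~ Gamma(a + (J−c)/2,
  b + ½Σ w_jk (u_j−u_k)²), τ_v ~ Gamma(a + J/2, b + ½Σ v_j²).

Two chains by default, chain 1 started at α = logit(observed
prevalence) and zeros, chain 2 at perturbed values (+0.5 on α and β,
τ = 10) to honour distinct starting values. Everything is deterministic
given the per-chain seeds. The production protocol is 100,000
iterations, 50,000 burn-in, thinning 2, two chains; desk-scale runs in
this repository use 10,000/5,000/2 (the analysis scripts accept
`--production-scale`).

The retained pointwise log-likelihood feeds WAIC. At production scale a
full draws×patients matrix is gigabytes, so the sampler always maintains
a streaming accumulator (running log-sum-exp for lppd, Welford variance
for p_waic) and keeps the explicit matrix only when small; tests verify
the two routes agree to 1e-10.

Correctness evidence beyond unit oracles: on a 2-area, 10-patient
instance with fixed precisions, the MCMC marginal of the identified
per-area log-odds matches a dense 4-dimensional grid-integration
posterior to total variation < 0.05; with the likelihood switched off
the sampler reproduces the Normal(0, 1/0.725) prior sd (1.1744) within
5%; τ draws with a frozen field match their Gamma full conditionals
(QQ/KS agreement).

## Diagnostics and comparison

- **PSRF (Gelman–Rubin)** — classic R̂ = sqrt(((n−1)/n·W + B/n)/W) from
  ≥2 chains, without the Brooks–Gelman df correction (second-order for
  the chain lengths used here). Values near 1 indicate convergence; the
  validation threshold for fixed effects is 1.1.
- **WAIC** — −2(lppd − p_waic) with patient-level pointwise units,
  conditional on the area effects (the standard choice for unit-level
  Bernoulli likelihoods); sample variances use the (s−1) denominator.
  Lower is better. `compare_models` ranks fits and reports deltas.

## Post-model outputs

- **Spatial fraction** φ = var(u)/(var(u)+var(v)) — the share of
  area-level variation attributable to spatial structure. From posterior
  draws, var(u) and var(v) are posterior means of the per-draw
  across-area empirical variances ((J−1) denominator); the operator
  order (variance inside, posterior mean outside) is a documented
  convention, as the source reports only "posterior mean" variance
  components. With the published distance-model components (0.807,
  0.223), φ = 0.78.
- **Relative risks** — per area-year, RR = observed poor count / expected
  count with E_jt = n_jt × pooled cohort prevalence. Pooling keeps the
  table exactly calibrated (ΣO = ΣE) and leaves temporal variation
  visible. Raw O/E, no posterior smoothing.
- **Weight-matrix sensitivity** — per coefficient,
  100·|m_d − m_a|/|m_a| on the posterior-mean log-odds scale (the
  printed percent changes in the motivating study are not derivable from
  its printed odds ratios under any simple definition, so this is a
  defined convention rather than a reproduction target). Near-zero
  reference coefficients are flagged undefined; sign flips warn.
- **Crosstabs** — poor/good counts, row percentages, and Pearson
  chi-square without continuity correction.

## Synthetic registry generator

The generator is the package's study population; its defaults encode the
cohort's published structure:

- 8×10 lattice of 20 km cells (80 areas, the state's LGA count);
  centroids at cell centres.
- Covariate marginals from the published characteristics table (e.g. age
  56–65: 0.403, PSA ≤10: 0.775, private institution: 0.728, metro:
  0.706; surgery-year distribution 2015–2021 with the 2021 drop).
  Area-level covariates (IRSD quartile, remoteness) are assigned per
  area and inherited by its patients. Covariates are sampled
  independently — between-covariate dependence (e.g. PSA by age) is not
  emulated and is a stated simplification.
- True effect sizes default to the published adjusted odds ratios of the
  distance-based model (e.g. public institution log 1.35, age 76–85
  log 2.90); δ₁ = 0.05, δ₂ = −0.01 give a mild concave year trend (the
  source does not print its temporal coefficients).
- BYM field: u drawn exactly from the sum-zero ICAR by eigendecomposing
  the graph Laplacian and sampling the non-null eigendirections with
  variances 1/(τ_u λ_i) (exact, feasible for a few hundred areas);
  v iid Normal. Defaults τ_u = 2, τ_v = 4.
  `icar_precision_for_variance` converts a target across-area field
  variance into the τ_u achieving it in expectation on a given graph,
  used to place synthetic fields on the published variance-component
  scale (var(u) 0.807, var(v) 0.223).
- The intercept default (−0.2754) was calibrated once by Monte-Carlo
  root-finding (`calibrate_intercept`) so the marginal poor-QoL
  prevalence is ≈36.4%, the cohort rate.
- Patient-to-area allocation is uniform by default; `area_weights`
  supports concentrated allocations (the sensitivity experiment uses
  71% metropolitan).

**Domain scores.** `simulate_domain_scores` attaches five discrete
EPIC-26-style scores consistent with each patient's outcome. Each
patient gets a latent cohort rank (poor patients fill the bottom
prevalence-fraction π̂, good the top, with a small guard gap at the
boundary); each domain maps a jittered copy of the rank through a
5-level step quantile function whose level masses are keyed to π̂ so the
cohort's empirical quartile cuts fall strictly inside level blocks. The
induced composite distribution then concentrates near {5, 10, 15, 20}
with below-median mass equal to π̂ — exactly the tie structure that lets
a median split produce a sub-50% poor rate, as the real cohort's 36%
must have had. Re-derivation reproduces the labels essentially exactly
for π̂ in ≈(0.26, 0.45); outside that range the generator warns. The
scores emulate skew and discreteness but not the real instrument's
item-level structure or inter-domain correlation pattern, so passing
tests validate the scoring pipeline's mechanics, not EPIC-26 psychometrics.

## Simulation experiments

**Parameter recovery.** Cohorts of 8,000 patients over the 80-area
lattice with a single nonzero effect β(public) = log 1.35, τ_u = 2,
τ_v = 4. A production-style fit (20,000/10,000/2 chains) must give all
fixed effects PSRF < 1.1 and cover the truth; 20 cheap single-chain
replicates (2,500 iterations) must cover every true coefficient in ≥18
of 20. With only ~100 patients per area and a weak field, the u/v
*split* is weakly identified (a known BYM property) — the total area
effect and the fixed effects are what recovery tests, and τ chains are
excluded from the PSRF threshold.

**Weight-matrix sensitivity.** Data are generated with the spatial field
drawn under the distance-band graph and fitted under both matrices; the
better WAIC should go to the distance-band fit. On a regular lattice
with even patient loads the two priors are practically
indistinguishable (the v component absorbs any local-flexibility
difference), so the experiment uses conditions that mirror what makes
the two matrices differ in the motivating geography: an 80-area
metro-block-plus-rural-arms map whose queen graph has areas with a
single neighbour while a 110 km band yields mean degree ≈28 (the study
matrices: mean 5.11 vs ~30), 71% metropolitan patient allocation, and
field variances on the published scale. n = 4,000 with 12,000-iteration
single-chain fits keeps the WAIC Monte-Carlo error (~0.5) below the
typical between-matrix gap (~+3), at ~11 minutes for ten replicates on
one CPU.

## Problem sizes and determinism

Desk-scale defaults throughout are chosen so the complete validation
suite runs in roughly twenty minutes on a single CPU; the production
MCMC protocol is available everywhere via configuration. All randomness
flows from explicit integer seeds (numpy `SeedSequence` spawning for
chains and generator stages); identical configuration + seed reproduces
byte-identical tables, and extending a run leaves the shared prefix of
the chain unchanged.

## Known limitations

- The BYM variance decomposition (hence φ from fitted draws) is weakly
  identified at registry-like data densities; φ is reported but its
  recovery is not asserted.
- The intrinsic CAR is improper; no proper (Leroux-type) alternative is
  implemented.
- Synthetic geography is planar and lattice-based; no spherical
  distances, no real shapefiles.
- Patient-level conditional WAIC is the only comparison criterion (no
  DIC/LOO), matching the motivating analysis.
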