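# spatqol

Bayesian spatio-temporal small-area analysis of poor patient-reported
quality of life (QoL) after prostatectomy.

## The problem

Twelve months after radical prostatectomy, men report their quality of
life through the EPIC-26 instrument: five domain scores (urinary
incontinence, urinary irritative/obstructive, bowel, sexual, hormonal),
each 0–100. Clinical registries want to know *where* and *when* poor
outcomes concentrate, which patient and area characteristics drive them,
and how robust the conclusions are to the way "neighbouring areas" is
defined. `spatqol` implements that full analysis for epidemiologists and
registry analysts:

- **Outcome derivation** — domain scores → cohort quartiles (1 worst … 4
  best) → composite score 5–20 → poor QoL = composite below the cohort
  median.
- **Spatial weights** — Queen contiguity (shared boundary vertex) and
  distance-band matrices over areal units, with GAL/GeoJSON IO and the
  smallest-connecting-band rule.
- **Model** — a multilevel logistic regression with
  Besag–York–Mollié area effects and a quadratic time trend, fitted by
  an adaptive Metropolis-within-Gibbs sampler written for this model.
- **Diagnostics** — Gelman–Rubin PSRF across chains; WAIC with
  patient-level pointwise likelihood; model ranking.
- **Outputs** — adjusted odds ratios with 95% credible intervals, the
  spatial fraction φ, observed/expected relative-risk tables by area and
  year, weight-matrix sensitivity of coefficients, prevalence crosstabs.
- **Synthetic registry** — a generator emulating the motivating cohort
  (~5,200 patients, 80 areas, 2015–2021, ~36% poor QoL), so the whole
  chain is testable without access-restricted registry data.

## The model

For patient *i* in area *j(i)*, surgery year *t_i* (centred):

```
y_i        ~ Bernoulli(p_i)
logit p_i  = α + x_i'β + δ₁ t_i + δ₂ t_i² + u_{j(i)} + v_{j(i)}

u | τ_u    ~ ICAR(W, τ_u)        (intrinsic CAR, Σu = 0)
v_j | τ_v  ~ N(0, 1/τ_v)
α, β, δ    ~ N(0, precision 0.725)   # 95% prior mass for OR in (0.1, 10)
τ_u, τ_v   ~ Gamma(0.5, 0.0005)
```

W is either weight matrix; fitting under both and comparing WAIC
quantifies the neighbourhood-definition sensitivity. See
`docs/methods.md` for the sampler, numerical conventions, and the
synthetic-data design.

## Worked example

The numbered scripts under `analysis/` run the study end to end on a
synthetic registry, writing all tables under `results/`:

```bash
python analysis/01_simulate_registry.py --seed 1
python analysis/02_score_outcomes.py
python analysis/03_build_weights.py
python analysis/04_fit_models.py          # two MCMC fits, desk scale
python analysis/05_compare_matrices.py
python analysis/06_rr_map.py
```

The first three steps print:

```
simulated 5238 patients over 80 areas
poor-QoL prevalence: 37.57%
spatial field var(u) = 0.125, var(v) = 0.235
scored 5238 patients; median composite 10
poor QoL: 1968 (37.57%)
agreement with generative labels: 100.00%
distance band: 20 km (smallest leaving no isolated area)
       matrix  mean  median  min  max       sd
        queen  6.70     8.0    3    8 1.656594
distance_band  3.55     4.0    2    4 0.593211
```

i.e. the generator hits the cohort's ~36–38% poor-QoL rate, the scoring
pipeline reproduces the generative labels exactly, and the two
neighbourhood definitions differ as expected (queen contiguity averages
6.7 neighbours on this lattice; the auto-selected 20 km band is the
smallest leaving no isolated area). Model fitting then reports, per
matrix, the WAIC, the worst PSRF, the adjusted odds ratio for public vs
private treating institution (true simulated value 1.35), and the
spatial fraction φ:

```
[queen] WAIC 6508.0; max PSRF 1.040 (alpha)
[queen] AOR public vs private: 1.23 (1.08, 1.41)
[queen] phi = 0.96 (var_u 0.303, var_v 0.013)
[distance_band] WAIC 6507.7; max PSRF 1.011 (age_group[66-75])
[distance_band] AOR public vs private: 1.23 (1.08, 1.41)
[distance_band] phi = 0.97 (var_u 0.308, var_v 0.010)
```

The 95% credible interval covers the simulated truth (1.35) under both
matrices; with the default generator's relatively weak spatial field, φ
from a fitted model mostly reflects the weakly identified u/v split (see
`docs/methods.md`). `05_compare_matrices.py` then ranks the two fits by
WAIC and tabulates the percent change of each coefficient between
matrices, and `06_rr_map.py` writes the observed/expected relative-risk
table and a GeoJSON with mean RR per area for choropleth tools:

```
        label        waic         lppd    p_waic  delta_waic
distance_band 6507.696044 -3182.853603 70.994419    0.000000
        queen 6508.013969 -3182.067198 71.939787    0.317925
better-fitting matrix: distance_band
...
559 area-year cells; RR range 0.00 to 2.66
calibration: sum observed 1968 = sum expected 1968.0
```

`analysis/07_experiments.py` runs small versions of the two simulation
experiments (parameter recovery; weight-matrix sensitivity with the
spatial field generated under the distance-band graph); the full
versions live in the test suite.

A `spatqol` console command exposes the same steps
(`simulate`, `score`, `weights`, `fit`, `diagnose`, `compare`,
`rrmap`, `pipeline`); `spatqol pipeline --out run/` executes everything
in one call.

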