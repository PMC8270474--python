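# Methods

`diseasemap` fits Bayesian disease-mapping models to area-level incidence
counts: the classical BYM convolution model for spatial smoothing of
standardized incidence ratios, and its additive spatio-temporal extension
with a first-order random-walk trend. This note documents the models, the
estimation machinery, the synthetic-data generator used for validation, and
the numerical and design choices a maintainer would want to know about.

## Data model and standardization

The unit of analysis is a small administrative district (we use "region"
throughout). Inputs are a line list of cases (region, sex, one of 12 age
groups, diagnosis year, ICD-O-3 stomach topography code C160–C166, C168,
C169), stratum population counts per region × sex × age group, a binary
first-order contiguity graph, and three region covariates: a
factor-analysis socio-economic index (SESI) and the immigrant and
Indigenous population percentages.

Observed counts are `Y_i = Σ_jk y_ijk` (sexes j, age groups k). Expected
counts use **internal indirect age-sex standardization**: reference rates
`r_jk = y_jk / n_jk` are computed from the pooled analysed data itself and
applied to each region's stratum populations, `E_i = Σ_jk r_jk n_ijk`.
Internal standardization forces `Σ_i E_i = Σ_i Y_i`, which the tests assert
to 1e-9. Strata with no population and no cases contribute zero (0/0 → 0);
cases in a zero-population stratum are a data-consistency error. Regions
with `E_i = 0` carry no likelihood information and are dropped with a
logged warning before fitting.

Sub-site stratification follows the ICD-O-3 coding: C160 is cardia, C161–
C166 and C168 are non-cardia, C169 is site-unspecified. Overall analyses
retain C169 by default; sub-site analyses exclude it. Diagnosis years are
binned into five 5-year periods (1992–1996 … 2012–2016) by default.

### Two standardization modes for period tables

For period-stratified tables there are two defensible choices of `E_it`,
and they answer different questions:

* `rates="within"` (the function default): reference rates are recomputed
  within each period, so `Σ_i E_it = Σ_i Y_it` per period. The resulting
  SIRs are purely *spatial* contrasts inside each period — any
  province-wide temporal trend is absorbed into `E`.
* `rates="pooled"`: the pooled rates `r_jk` of the unstratified analysis
  are applied once per region and the total expectation is spread across
  periods in proportion to person-time (period length, with the population
  held constant). Conservation then holds globally but not per period —
  deliberately, because this is the mode that leaves province-wide
  temporal trends in the data.

The spatio-temporal model *must* be fed pooled-rate tables: under
within-period standardization the global period effects `γ_t + φ_t` are
unidentified by construction (the data contain no period-level signal), a
fact we verified empirically — planted trends of ±0.2 on the log scale are
recovered under pooled rates and vanish entirely under within-period
rates. All spatio-temporal fitting paths therefore default to
`rates="pooled"`.

## The models

Spatial model (counts `Y_i ~ Poisson(λ_i E_i)`):

    log λ_i = α + βᵀx_i + u_i + η_i

* `u_i ~ N(0, σ²_u)` — unstructured heterogeneity;
* `η` — intrinsic CAR (ICAR) field: `η_i | η_{-i} ~ N(mean of neighbors,
  σ²_η / d_i)` with `d_i` the neighbor count; jointly this is the improper
  Gaussian with density ∝ exp(−Σ_{i~j}(η_i−η_j)²/(2σ²_η)), rank `n − c`
  for `c` connected components.

Spatio-temporal model (additive, no space-time interaction):

    log λ_it = α + βᵀx_i + u_i + η_i + γ_t + φ_t

* `γ_t ~ N(0, σ²_γ)` — exchangeable period effect;
* `φ` — first-order random walk, RW(1): endpoints conditionally
  `N(φ_{t±1}, σ²_φ)`, interior `N((φ_{t−1}+φ_{t+1})/2, σ²_φ/2)`; rank
  `T − 1`.

Priors: improper flat prior on `α` (posterior propriety requires `ΣY > 0`,
which is enforced), `β_j ~ N(0, 1000)` read as **variance** 1000 (the
common precision-0.001 convention is numerically identical; configurable
via `PriorSpec`), and `Gamma(0.1, 0.01)` (shape, rate) on every precision
`τ = 1/σ²`.

Weights are strictly binary contiguity, never row-standardised, in both
the CAR prior and Moran's I (which uses the `n/S0` normalisation with
`S0 = 2|E|`).

### Identifiability

The ICAR and RW(1) priors are invariant to level shifts, which are
confounded with `α` (and with `γ` for `φ`). After every sweep `η` and `φ`
are recentred to sum to zero and the deducted means are added to `α`.
Both transforms leave the posterior exactly invariant: the likelihood
depends only on the sums being preserved, the structured priors are
shift-free, and `α`'s prior is flat. (Absorbing the `φ` mean into `γ`
instead would *not* be invariant, because `γ` carries a proper Gaussian
prior.) Islands (degree-0 regions) have no CAR conditional; their `η` is
pinned at 0, their variation is carried by `u_i`, and the precision update
uses the rank correction `n − c` with islands counted as components. With
islands present the recentring-into-α step is only approximately
invariant (island linear predictors do not cancel); connected study
graphs — the tested path — are exact.

## Estimation: Metropolis-within-Gibbs

The estimator is MCMC from the exact model and priors:

* **Latent fields**: single-site random-walk Metropolis. Sites whose full
  conditionals are mutually independent are updated in one vectorised
  block: all `u_i` at once (independent given the rest), `η` by colour
  classes of a proper greedy graph colouring, `γ` at once, `φ` by even/odd
  periods. This is exactly single-site updating, executed in parallel.
* **α and β**: scalar random-walk Metropolis. Covariates are centred
  internally (the recorded intercept is shifted back), which removes the
  dominant α–β posterior correlation.
* **Level-swap moves**: an extra Metropolis move proposes `α → α + d`,
  `u → u − d` (and analogously for `γ`), for which the likelihood is
  invariant and only the Gaussian prior enters the ratio. This decorrelates
  the intercept from the random-effect level and was the single largest
  mixing improvement in development.
* **Precisions**: conjugate Gamma draws, `τ ~ Gamma(a + r/2, b + q/2)`
  with `q` the structure's quadratic form and `r` its rank (`n` iid,
  `n − c` ICAR, `T − 1` RW(1)).
* **Adaptation**: per-block proposal scales adapt toward 0.44 acceptance
  in batches of 50 sweeps during burn-in only and are frozen afterwards,
  so the retained draws come from a fixed, detailed-balance-preserving
  kernel.

Chains start from overdispersed initial values seeded from a single user
seed via `numpy.random.SeedSequence` spawning, so runs are reproducible
and chains independent. Default budget: 4 chains × 30,000 iterations,
10,000 burn-in, thinning 10. Convergence is monitored by the split-chain
potential scale reduction factor R̂ for all scalar parameters; R̂ > 1.1
sets `converged = False` on the results object (a warning, never an
exception).

Correctness anchors: on a 3-region path graph with fixed unit precisions,
the sampler's posterior mean of α agrees with a deterministic
Gauss-Hermite/grid quadrature oracle to well under 0.03 (observed
difference ≈ 0.001); a 2-region × 2-period model is checked the same way.
With the likelihood removed, the posterior is the prior: that case is
sampled *exactly* by ancestral sampling (precisions from their Gamma
prior, fields from the constrained ICAR/RW(1) generators), which verifies
prior parameters and rank conventions independently of kernel mixing.

## Spatial-dependency diagnostics

Before any Bayesian fit, a non-spatial Poisson GLM
`log μ_i = log E_i + a + bᵀx_i` is fitted by in-repo IRLS (convergence at
relative log-likelihood change < 1e-10, max 100 iterations; validated
against a generic optimiser and statsmodels to 1e-6/1e-8). The map of
unexplained variation `Y_i/μ̂_i` is then tested for clustering with
Moran's I under a permutation null: one-sided upper p-value
`(1 + #{I_perm ≥ I_obs}) / (1 + n_perm)`, permuting value-to-region
assignment with a seeded generator. The permutation test is exact under
exchangeability, makes no asymptotic assumption at n ≈ 96, and its +1
correction keeps p > 0. Calibration is asserted: on 200 null datasets the
rejection rate at α = 0.05 falls in [0.02, 0.09].

## Socio-economic index

SESI is a one-factor summary of income, employment and education:
indicators are z-standardized, a single-factor loading vector is extracted
from the correlation matrix by the **iterated principal-factor** method
(SMC initial communalities, convergence when communalities move < 1e-8,
max 500 iterations), and scores use the regression method `Z R⁻¹ Λ`. The
sign is fixed so income loads positively. Scores are invariant to affine
rescaling of any indicator; an optional affine rescale maps them onto a
configured range. The exact factor-analysis variant used to build any
particular published index is rarely documented; this module's contract is
the invariants above, not bit-agreement with any external implementation.

## Posterior reportables

* **IRR tables**: per covariate, `exp` of the (median, 2.5%, 97.5%)
  quantiles of the pooled β draws. Quantiles are equivariant under
  monotone transforms, so these are exactly the IRR quantiles, and
  negating β yields exactly reciprocal, swapped bounds. A covariate is
  flagged significant when the interval excludes 1.
* **Smoothed district risk**: posterior median and 95% interval of
  `exp(u_i + η_i)` (× `exp(γ_t + φ_t)` per period), computed the same
  way. A district is "elevated" when its whole 95% interval lies above 1 —
  an exceedance-style rule chosen because published maps rarely state
  their cut; it is not expected to match any particular published count.
* **Risk categories**: quintiles of the posterior median by default, or
  fixed user breaks; ties go to the lower category; per-category counts
  are returned for map legends.

## Synthetic registry generator

The generator is the generative twin of the models and defines the study
conditions for every simulation-based test:

* 96 regions on an 8 × 12 rook lattice; 5 five-year periods; 2 sexes × 12
  age groups; total population 1.17 M with lognormal region-size spread
  (σ = 0.4 on the log scale).
* Age-specific baseline rates rise monotonically from 0.4 to 80 per
  100,000 person-years across the 12 age groups, with a population pyramid
  that makes the *case count* peak in the 75–79 group; male rates are
  about twice female. Together these give ≈ 2,500–3,600 cases over the
  25-year window — the sparsity regime of a mid-sized provincial registry.
* True risks are built exactly as the model assumes:
  `exp(α + βᵀx + u + η [+ γ_t + φ_t])`, with default coefficients
  SESI −0.082, immigrant +0.003, Indigenous +0.001 (IRRs ≈ 0.92, 1.003,
  1.001) and variance components σ²_u = 0.02, σ²_η = 0.10,
  σ²_γ = 0.002, σ²_φ = 0.01 — spatially-structured variation dominant,
  temporal variation modest.
* Covariates are spatially smooth (SESI, rescaled to 1–9) or patchy
  logistic transforms of smooth fields plus noise (the two percentage
  shares).
* Structured fields (`η`, and `φ` via a path graph) are drawn **exactly**
  on the sum-to-zero subspace by eigendecomposition of the graph
  Laplacian: coordinates along eigenvectors with eigenvalue λ > 0 are
  independent `N(0, σ²/λ)`. This route shares no code with the fitter's
  conditional updates, so recovery tests are a genuine cross-check, and it
  gives the testable moment `E[η'Qη] = σ²(n − c)`.
* Stratum counts are Poisson; records are exploded to a line list with
  uniform years within period and topography codes drawn from a
  configurable mix (31% C160, 7% each of the seven non-cardia codes, 20%
  C169, matching a realistic sub-site distribution); sub-sites are
  region-independent by default.
* Optional planted hotspots multiply selected regions' risk by a known
  factor; `truth.json` records every latent quantity.

What the generator does **not** emulate: geocoding error and
misassignment of cases to regions, population drift over time (the
constant-population assumption is built in), age-period-cohort structure,
sub-site-specific spatial patterns (unless the stress option is used),
reporting delay and under-ascertainment. Passing recovery tests therefore
demonstrates statistical correctness of the machinery under the stated
model, not robustness to those real-data complications.

## Problem sizes and budgets used by the test suite

Simulation-based checks are sized to be decisive yet routine to run:
parameter recovery uses 100 replicate 96-region registries at a reduced
budget (2 chains × 5,000 iterations, 2,000 burn-in) — the observed mean
bias of the SES coefficient is ≈ 0.000–0.003 on the log scale with ≈ 95%
interval coverage; trend recovery uses 20 replicates; the permutation-test
calibration uses 200 null datasets × 999 permutations; distributional
checks (precision conjugacy, prior recovery) use 10⁵–1.5 × 10⁵ draws.
The quadrature oracles use grids of 0.02–0.08 with 21–31 Gauss-Hermite
nodes, an order of magnitude finer than the tolerances they certify.

## Known limitations

* Estimation is MCMC; no attempt is made to reproduce approximate-inference
  shortcuts, and very large graphs (thousands of regions) would need a
  sparser update schedule than the current dense Laplacian
  eigendecomposition in the *generator* (the fitter itself is sparse).
* The additive spatio-temporal model has no space-time interaction;
  region-specific trends are out of scope.
* Island handling (η pinned at 0, approximate recentring) is structural
  rather than numerically certified; studies with disconnected graphs
  should check sensitivity.
* The high-risk ("elevated") rule and quintile categories are conventions;
  published maps built with other rules will not match count-for-count.
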