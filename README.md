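# diseasemap

Bayesian disease mapping for area-level incidence counts: spatial and
spatio-temporal BYM-type Poisson regression with intrinsic-CAR spatial
smoothing, fitted by MCMC, together with everything around it — indirect
age-sex standardization, Moran's I spatial-dependency diagnostics, a
factor-analysis socio-economic index, map-ready risk tables, and a
synthetic registry generator for end-to-end validation.

It is written for epidemiologists and biostatisticians who have a cancer-
registry-style line list (cases with region, sex, age group, diagnosis
year and an ICD-O-3 topography code), stratum population counts, and a
district contiguity structure, and who want smoothed district-specific
risk estimates and covariate incidence risk ratios (IRRs) with credible
intervals.

## The model

Counts per district follow `Y_i ~ Poisson(λ_i E_i)`, where `E_i` are
internally standardized expected counts, `E_i = Σ_jk (y_jk/n_jk) n_ijk`
over sex × age strata, and the relative risk is log-linear:

    log λ_i = α + βᵀx_i + u_i + η_i                          (spatial)
    log λ_it = α + βᵀx_i + u_i + η_i + γ_t + φ_t             (spatio-temporal)

with `u_i ~ N(0, σ²_u)` unstructured heterogeneity, `η` an intrinsic CAR
field (`η_i | η_{-i} ~ N(neighbor mean, σ²_η/d_i)` on the binary
contiguity graph), `γ_t` exchangeable period effects and `φ` a
first-order random walk. Priors: flat α, `β ~ N(0, 1000)`, and
`Gamma(0.1, 0.01)` on each precision. Estimation is Metropolis-within-
Gibbs with conjugate precision updates, sum-to-zero identification of η
and φ, adaptive proposals frozen after burn-in, and split-chain R̂
monitoring. See `docs/methods.md` for the full account.

## Worked example

Simulate a registry with known ground truth (96 districts, 25 years,
~2,500 cases; the true SESI coefficient is −0.082, IRR ≈ 0.92), check for
spatial dependency, and fit the spatial model:

```python
import diseasemap as dm

registry = dm.simulate_registry(dm.SimulationScenario(seed=1))
ids = registry.graph.region_ids
table = dm.expected_counts(registry.cases, registry.populations, ids)

glm = dm.fit_poisson_glm(table.Y, table.E, registry.covariates.matrix())
ratios = dm.residual_risk_ratio(table.Y, glm)
moran = dm.morans_i_permutation_test(ratios, registry.graph,
                                     n_permutations=999, seed=1)
print(f"Moran's I = {moran.i_value:.4f}, p = {moran.p_value:.3f}")

model = dm.SpatialCountModel(table, registry.graph,
                             covariates=registry.covariates)
res = model.fit(n_chains=4, n_iterations=12000, n_burnin=4000, thin=4, seed=1)
print(res.summary())
```

Output:

```
Moran's I = 0.2187, p = 0.005
Spatial BYM Poisson model
========================================================================
Regions:    96    Chains: 4  Iterations: 12000  Burn-in: 4000  Thin: 4
Convergence: max R-hat = 1.015 (beta:pct_immigrant)
------------------------------------------------------------------------
parameter                 median      mean      2.5%     97.5%
alpha                     0.3732    0.3708    0.0455    0.6908
beta:sesi                -0.0945   -0.0942   -0.1499   -0.0377
beta:pct_immigrant        0.0033    0.0033   -0.0014    0.0079
beta:pct_indigenous       0.0007    0.0007   -0.0029    0.0042
tau_u                    31.4850   46.4547   11.2513  162.7627
tau_eta                   8.1176   10.5768    3.6591   33.0031
------------------------------------------------------------------------
covariate (IRR)              IRR      2.5%     97.5%
sesi                      0.9098    0.8608    0.9630  *
pct_immigrant             1.0033    0.9986    1.0080
pct_indigenous            1.0007    0.9971    1.0042
========================================================================
```

Reading the output: the permutation test confirms spatial clustering of
the GLM-unexplained risk (I = 0.22, p = 0.005), justifying the spatial
model. The fitted SESI IRR of 0.910 (95% CrI 0.861–0.963, flagged `*`
because the interval excludes 1) recovers the simulated truth of 0.921:
each unit of the socio-economic index reduces incidence risk by ~9%. The
two population-share covariates are correctly found null. `tau_u` and
`tau_eta` are the precisions of the unstructured and spatially structured
random effects. `res.region_risk()` then gives each district's smoothed
relative risk `exp(u_i + η_i)` with its interval and an "elevated" flag
(interval entirely above 1) — 10 districts here —, and
`res.region_risk_categories()` adds quintile categories with per-category
counts for choropleth legends.

The same workflow runs from the shell:

```sh
diseasemap simulate --out data --seed 1
diseasemap run --config config.yaml --seed 1 --out results
```

where the YAML config names the four input files, the strata to analyse
(overall / male / female / cardia / non_cardia), the MCMC budget, and
whether to add the spatio-temporal fits (`periods: true`).

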