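"""Registry-like synthetic data with the exact structure the models assume.

The generator is the generative twin of the fitted models: region risks
are built as exp(alpha + beta.x_i + u_i + eta_i [+ gamma_t + phi_t]) with
u iid Gaussian, eta an intrinsic-CAR field, gamma exchangeable and phi a
first-order random walk; stratum case counts are Poisson with age- and
sex-specific baseline rates times the region(-period) risk, then exploded
into line-list case records with ICD-O-3 topography codes.

Structured fields are drawn *exactly* on the sum-to-zero subspace via an
eigendecomposition of the graph Laplacian — deliberately a different
route than the fitter's conditional updates, so generator and sampler
share no code path and recovery tests are a genuine cross-check.

Default scenario shape mirrors a provincial cancer registry: 96 districts
on an 8 x 12 rook lattice, 5 five-year diagnosis periods, 2 sexes x 12
age groups, an age-incidence profile whose case counts peak in the 75-79
group, and ~3,000-3,500 total cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .cohort import AGE_GROUPS, SEXES, TOPOGRAPHY_CODES, DEFAULT_PERIODS, period_label
from .covariates import CovariateTable
from .graph import RegionGraph, build_adjacency, make_lattice


class ScenarioError(ValueError):
    pass


#: population share per age group (youngest to oldest) — a steady
#: provincial pyramid with ~45% under 35
AGE_POP_SHARES = np.array([0.45, 0.065, 0.065, 0.065, 0.07, 0.065,
                           0.06, 0.05, 0.04, 0.03, 0.02, 0.02])

#: baseline gastric-cancer incidence per person-year by age group; rates
#: rise monotonically with age while case counts peak at 75-79 because the
#: population pyramid narrows faster than the rate rises
AGE_RATES = np.array([0.4, 1.5, 2.5, 4, 7, 12, 20, 32, 48, 65, 75, 80]) * 1e-5

#: male:female incidence multipliers (~2:1 male excess)
SEX_RATE_FACTOR = {"M": 1.35, "F": 0.68}

#: sub-site mix of emitted topography codes: 31% cardia (C160), 49%
#: non-cardia spread evenly over C161-C166/C168, 20% unspecified (C169)
DEFAULT_SUBSITE_MIX = {"C160": 0.31, **{c: 0.07 for c in
                       ("C161", "C162", "C163", "C164", "C165", "C166", "C168")},
                       "C169": 0.20}


@dataclass
class SimulationScenario:
    """Ground-truth configuration for one synthetic registry."""

    nrows: int = 8
    ncols: int = 12
    edges: list | None = None          # explicit graph instead of a lattice
    region_ids: tuple | None = None
    n_periods: int = 5
    total_population: float = 1_170_000.0
    alpha: float = 0.0
    beta: dict = dc_field(default_factory=lambda: {
        "sesi": -0.082, "pct_immigrant": 0.003, "pct_indigenous": 0.001})
    sigma2_u: float = 0.02
    sigma2_eta: float = 0.10
    sigma2_gamma: float = 0.002
    sigma2_phi: float = 0.01
    phi_true: np.ndarray | None = None  # explicit temporal trend (overrides sigma2_phi)
    planted_regions: tuple = ()
    planted_multiplier: float = 2.0
    subsite_mix: dict = dc_field(default_factory=lambda: dict(DEFAULT_SUBSITE_MIX))
    region_size_sd: float = 0.4         # lognormal spread of region populations
    seed: int = 0

    def __post_init__(self):
        if self.edges is None and (self.nrows < 2 or self.ncols < 2):
            raise ScenarioError("lattice must be at least 2 x 2")
        for name in ("sigma2_u", "sigma2_eta", "sigma2_gamma", "sigma2_phi"):
            if getattr(self, name) < 0:
                raise ScenarioError(f"{name} must be >= 0")
        if self.n_periods < 1:
            raise ScenarioError("n_periods must be >= 1")
        if abs(sum(self.subsite_mix.values()) - 1.0) > 1e-9:
            raise ScenarioError("subsite_mix must sum to 1")
        unknown = set(self.subsite_mix) - set(TOPOGRAPHY_CODES)
        if unknown:
            raise ScenarioError(f"unknown topography codes in subsite_mix: {sorted(unknown)}")

    def build_graph(self) -> RegionGraph:
        if self.edges is not None:
            return build_adjacency(self.edges, self.region_ids)
        return make_lattice(self.nrows, self.ncols)

    def period_scheme(self) -> tuple:
        if self.n_periods == 5:
            return DEFAULT_PERIODS
        return tuple((1992 + 5 * t, 1996 + 5 * t) for t in range(self.n_periods))


def icar_basis(graph: RegionGraph) -> tuple[np.ndarray, np.ndarray]:
    """Eigenbasis of the graph Laplacian restricted to non-null directions.

    Returns (V, lam) with V of shape (n, n - c): the eigenvectors with
    strictly positive eigenvalue.  The excluded null space is spanned by
    per-component constants, so any field built from V sums to zero on
    every connected component.
    """
    n = graph.n_regions
    L = np.zeros((n, n))
    for a, b in zip(graph.edge_i, graph.edge_j):
        L[a, a] += 1
        L[b, b] += 1
        L[a, b] -= 1
        L[b, a] -= 1
    vals, vecs = np.linalg.eigh(L)
    keep = vals > 1e-9 * max(vals.max(), 1.0)
    return vecs[:, keep], vals[keep]


def simulate_structured_field(graph: RegionGraph, sigma2: float, seed,
                              size: int | None = None) -> np.ndarray:
    """Exact draw(s) from the intrinsic CAR distribution on the sum-to-zero subspace.

    The joint ICAR density is proportional to exp(-q(eta) / (2 sigma2))
    with q the pairwise-difference quadratic form; in the Laplacian
    eigenbasis the non-null coordinates are independent Gaussians with
    variance sigma2 / lambda_k.  ``seed`` may be an int or a Generator.
    Returns shape (n,) or (size, n).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    V, lam = icar_basis(graph)
    m = 1 if size is None else size
    z = rng.normal(size=(m, V.shape[1]))
    fields = (z * np.sqrt(sigma2 / lam)) @ V.T
    return fields[0] if size is None else fields


def _spatial_covariates(graph: RegionGraph, rng: np.random.Generator) -> CovariateTable:
    """Spatially smooth SES index plus patchy immigrant/Indigenous shares."""
    n = graph.n_regions

    def smooth(scale):
        f = simulate_structured_field(graph, 1.0, rng)
        return scale * f / max(f.std(), 1e-12)

    sesi_raw = smooth(1.0) + 0.3 * rng.normal(size=n)
    lo, hi = sesi_raw.min(), sesi_raw.max()
    sesi = 1.0 + 8.0 * (sesi_raw - lo) / max(hi - lo, 1e-12)

    def expit(x):
        return 1.0 / (1.0 + np.exp(-x))

    pct_imm = 100.0 * expit(-2.0 + 1.5 * smooth(1.0) + 0.8 * rng.normal(size=n))
    pct_ind = 100.0 * expit(-2.2 + 1.8 * smooth(1.0) + 0.8 * rng.normal(size=n))
    return CovariateTable(graph.region_ids, sesi, pct_imm, pct_ind)


@dataclass
class SimulatedRegistry:
    """One synthetic registry: line list, populations, covariates, graph, truth."""

    cases: pd.DataFrame
    populations: pd.DataFrame
    covariates: CovariateTable
    graph: RegionGraph
    truth: dict

    def write(self, outdir) -> dict:
        """Write the CSV dialects consumed by the rest of the package, plus truth.json."""
        import json
        from pathlib import Path

        from .graph import write_edge_csv

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "cases": outdir / "cases.csv",
            "populations": outdir / "populations.csv",
            "covariates": outdir / "covariates.csv",
            "edges": outdir / "edges.csv",
            "truth": outdir / "truth.json",
        }
        self.cases.to_csv(paths["cases"], index=False)
        self.populations.to_csv(paths["populations"], index=False)
        self.covariates.to_frame().to_csv(paths["covariates"], index=False)
        write_edge_csv(self.graph, paths["edges"])
        truth = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in self.truth.items()}
        paths["truth"].write_text(json.dumps(truth, indent=1))
        return {k: str(v) for k, v in paths.items()}


def simulate_registry(scenario: SimulationScenario, seed: int | None = None) -> SimulatedRegistry:
    """Generate a full synthetic registry from a scenario's ground truth."""
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    graph = scenario.build_graph()
    n = graph.n_regions
    region_ids = graph.region_ids
    scheme = scenario.period_scheme()
    T = scenario.n_periods
    years_per_period = np.array([hi - lo + 1 for lo, hi in scheme], dtype=float)

    covariates = _spatial_covariates(graph, rng)

    # latent truth
    u = rng.normal(0.0, np.sqrt(scenario.sigma2_u), size=n)
    eta = (simulate_structured_field(graph, scenario.sigma2_eta, rng)
           if scenario.sigma2_eta > 0 else np.zeros(n))
    if T > 1:
        gamma = rng.normal(0.0, np.sqrt(scenario.sigma2_gamma), size=T)
        if scenario.phi_true is not None:
            phi = np.asarray(scenario.phi_true, dtype=float)
            if len(phi) != T:
                raise ScenarioError("phi_true length must equal n_periods")
        elif scenario.sigma2_phi > 0:
            phi = simulate_structured_field(make_lattice(1, T), scenario.sigma2_phi, rng)
        else:
            phi = np.zeros(T)
    else:
        gamma = np.zeros(1)
        phi = np.zeros(1)

    xbeta = np.zeros(n)
    for name, b in scenario.beta.items():
        if name not in CovariateTable.names:
            raise ScenarioError(f"unknown covariate in beta: {name!r}")
        xbeta = xbeta + b * getattr(covariates, name)
    log_risk = scenario.alpha + xbeta + u + eta
    if scenario.planted_regions:
        planted = [graph.index_of(r) for r in scenario.planted_regions]
        log_risk = log_risk.copy()
        log_risk[planted] += np.log(scenario.planted_multiplier)
    risk_it = np.exp(log_risk[:, None] + gamma[None, :] + phi[None, :])  # (n, T)

    # stratum populations: lognormal region sizes x fixed pyramid x even sexes
    w = np.exp(rng.normal(0.0, scenario.region_size_sd, size=n))
    region_pop = scenario.total_population * w / w.sum()
    pop_rows = []
    n_ijk = np.zeros((n, 2, 12))
    for i, rid in enumerate(region_ids):
        for j, sex in enumerate(SEXES):
            for k, ag in enumerate(AGE_GROUPS):
                cnt = int(round(region_pop[i] * 0.5 * AGE_POP_SHARES[k]))
                n_ijk[i, j, k] = cnt
                pop_rows.append({"region_id": rid, "sex": sex, "age_group": ag, "count": cnt})
    populations = pd.DataFrame(pop_rows)

    # Poisson stratum counts and line-list explosion
    sex_fac = np.array([SEX_RATE_FACTOR[s] for s in SEXES])
    mu = (n_ijk[:, :, :, None]
          * (AGE_RATES[None, None, :, None] * sex_fac[None, :, None, None])
          * years_per_period[None, None, None, :]
          * risk_it[:, None, None, :])
    counts = rng.poisson(mu)

    codes = list(scenario.subsite_mix.keys())
    probs = np.array([scenario.subsite_mix[c] for c in codes])
    case_rows = []
    for i, rid in enumerate(region_ids):
        for j, sex in enumerate(SEXES):
            for k, ag in enumerate(AGE_GROUPS):
                for t, (lo, hi) in enumerate(scheme):
                    c = counts[i, j, k, t]
                    if c == 0:
                        continue
                    years = rng.integers(lo, hi + 1, size=c)
                    topos = rng.choice(codes, size=c, p=probs)
                    for yr, tp in zip(years, topos):
                        case_rows.append({"region_id": rid, "sex": sex, "age_group": ag,
                                          "year": int(yr), "topography": tp})
    cases = pd.DataFrame(case_rows, columns=["region_id", "sex", "age_group", "year", "topography"])
    if counts.sum() < 10:
        import warnings
        warnings.warn(f"scenario yields only {int(counts.sum())} expected cases; "
                      "recovery tests need non-degenerate data", stacklevel=2)

    truth = {
        "alpha": scenario.alpha,
        "beta": dict(scenario.beta),
        "sigma2_u": scenario.sigma2_u, "sigma2_eta": scenario.sigma2_eta,
        "sigma2_gamma": scenario.sigma2_gamma, "sigma2_phi": scenario.sigma2_phi,
        "u": u, "eta": eta, "gamma": gamma, "phi": phi,
        "log_risk": log_risk, "risk": risk_it,
        "planted_regions": list(scenario.planted_regions),
        "planted_multiplier": scenario.planted_multiplier,
        "periods": [period_label(p) for p in scheme],
        "n_cases": int(counts.sum()),
        "seed": scenario.seed if seed is None else seed,
    }
    return SimulatedRegistry(cases, populations, covariates, graph, truth)
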