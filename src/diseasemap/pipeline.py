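"""Config-driven orchestration of the full mapping analysis.

Sequence per run: load inputs -> non-spatial Poisson GLM and Moran's I
spatial-dependency check -> per-stratum spatial fits -> optional
per-stratum spatio-temporal fits -> IRR and smoothed-risk tables, with a
machine-readable manifest.  Strata are drawn from a fixed vocabulary
(overall, male, female, cardia, non_cardia, unspecified); a stratum whose
filter yields no cases is skipped with a logged reason, never an error.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cohort, covariates as cov_mod, diagnostics, graph as graph_mod
from .model import PriorSpec, SamplerOptions, SpatialCountModel, SpatioTemporalCountModel
from .summaries import categorize_risk

logger = logging.getLogger(__name__)

STRATA = {
    "overall": {},
    "male": {"sex": "M"},
    "female": {"sex": "F"},
    "cardia": {"subsite": "cardia"},
    "non_cardia": {"subsite": "non_cardia"},
    "unspecified": {"subsite": "unspecified"},
}


class ConfigValidationError(ValueError):
    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in self.errors))


@dataclass
class RunConfig:
    cases: str
    populations: str
    covariates: str
    adjacency: str
    output: str = "out"
    strata: tuple = ("overall",)
    periods: bool = False
    seed: int = 0
    log_level: str = "INFO"
    n_chains: int = 4
    n_iterations: int = 30_000
    n_burnin: int = 10_000
    thin: int = 10
    beta_var: float = 1000.0
    precision_shape: float = 0.1
    precision_rate: float = 0.01
    n_permutations: int = 999
    use_covariates: bool = True
    risk_breaks: tuple | None = None

    def sampler_options(self, seed: int) -> SamplerOptions:
        return SamplerOptions(n_chains=self.n_chains, n_iterations=self.n_iterations,
                              n_burnin=self.n_burnin, thin=self.thin, seed=seed)

    def priors(self) -> PriorSpec:
        return PriorSpec(beta_var=self.beta_var, precision_shape=self.precision_shape,
                         precision_rate=self.precision_rate)


_SCHEMA = {
    "inputs": {"cases", "populations", "covariates", "adjacency"},
    "mcmc": {"n_chains", "n_iterations", "n_burnin", "thin"},
    "priors": {"beta_var", "precision_shape", "precision_rate"},
    "moran": {"n_permutations"},
}
_TOP_KEYS = {"inputs", "mcmc", "priors", "moran", "strata", "periods", "seed",
             "output", "log_level", "use_covariates", "risk_breaks"}


def validate_config(raw) -> RunConfig:
    """Validate a parsed YAML/JSON mapping (or YAML text) into a RunConfig.

    Every unknown key is reported; errors are aggregated into a single
    ConfigValidationError so typos surface all at once.
    """
    if isinstance(raw, str):
        raw = yaml.safe_load(raw)
    if not isinstance(raw, dict):
        raise ConfigValidationError(["config must be a mapping"])
    errors = []
    for key in raw:
        if key not in _TOP_KEYS:
            errors.append(f"unknown key {key!r}")
    for section, allowed in _SCHEMA.items():
        sub = raw.get(section, {})
        if not isinstance(sub, dict):
            errors.append(f"section {section!r} must be a mapping")
            continue
        for key in sub:
            if key not in allowed:
                errors.append(f"unknown key {section}.{key!r}")
    inputs = raw.get("inputs", {})
    for req in ("cases", "populations", "covariates", "adjacency"):
        if not isinstance(inputs, dict) or req not in inputs:
            errors.append(f"missing required input path inputs.{req}")
    strata = tuple(raw.get("strata", ("overall",)))
    for s in strata:
        if s not in STRATA:
            errors.append(f"unknown stratum {s!r}; valid: {sorted(STRATA)}")
    mcmc = raw.get("mcmc", {}) if isinstance(raw.get("mcmc", {}), dict) else {}
    n_iter = mcmc.get("n_iterations", 30_000)
    n_burn = mcmc.get("n_burnin", 10_000)
    if n_burn >= n_iter:
        errors.append(f"mcmc.n_burnin ({n_burn}) must be < mcmc.n_iterations ({n_iter})")
    if mcmc.get("thin", 10) < 1:
        errors.append("mcmc.thin must be >= 1")
    if errors:
        raise ConfigValidationError(errors)
    priors = raw.get("priors", {})
    moran = raw.get("moran", {})
    return RunConfig(
        cases=inputs["cases"], populations=inputs["populations"],
        covariates=inputs["covariates"], adjacency=inputs["adjacency"],
        output=raw.get("output", "out"), strata=strata,
        periods=bool(raw.get("periods", False)), seed=int(raw.get("seed", 0)),
        log_level=raw.get("log_level", "INFO"),
        n_chains=mcmc.get("n_chains", 4), n_iterations=n_iter, n_burnin=n_burn,
        thin=mcmc.get("thin", 10),
        beta_var=priors.get("beta_var", 1000.0),
        precision_shape=priors.get("precision_shape", 0.1),
        precision_rate=priors.get("precision_rate", 0.01),
        n_permutations=moran.get("n_permutations", 999),
        use_covariates=bool(raw.get("use_covariates", True)),
        risk_breaks=tuple(raw["risk_breaks"]) if raw.get("risk_breaks") else None,
    )


def load_config(path) -> RunConfig:
    return validate_config(Path(path).read_text())


def _load_inputs(config: RunConfig):
    adjacency = Path(config.adjacency)
    if adjacency.suffix.lower() == ".gal":
        graph = graph_mod.read_gal(adjacency)
    else:
        graph = graph_mod.read_edge_csv(adjacency)
    cases = cohort.read_cases_csv(config.cases)
    pops = cohort.read_populations_csv(config.populations)
    covs = cov_mod.read_covariates_csv(config.covariates, graph.region_ids)
    return graph, cases, pops, covs


def _stratum_seed(base: int, k: int) -> int:
    return int((base + 7919 * (k + 1)) % (2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the analysis sequence; return (and write) the run manifest."""
    t_start = time.time()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "strata": {}, "files": {}, "skipped": {},
                "versions": _versions()}

    try:
        graph, cases, pops, covs = _load_inputs(config)
    except Exception as exc:
        raise RuntimeError(f"stage 'load_inputs' failed: {exc}") from exc
    X = covs if config.use_covariates else None

    # spatial-dependency diagnostics on the overall counts
    try:
        table = cohort.expected_counts(cases, pops, graph.region_ids)
        table, dropped = cohort.drop_zero_expected(table)
        dgraph = subgraph(graph, table.region_ids) if dropped else graph
        Xmat = covs.matrix()[[graph.index_of(r) for r in table.region_ids]] if config.use_covariates else None
        glm = diagnostics.fit_poisson_glm(table.Y, table.E, Xmat)
        ratios = diagnostics.residual_risk_ratio(table.Y, glm)
        moran = diagnostics.morans_i_permutation_test(
            ratios, dgraph, n_permutations=config.n_permutations, seed=config.seed)
        diag = {"moran": moran.to_dict(),
                "glm_coefficients": glm.coefficients.tolist(),
                "glm_converged": glm.converged, "dropped_regions": dropped}
        diag_path = outdir / "diagnostics.json"
        diag_path.write_text(json.dumps(diag, indent=1))
        residual_path = outdir / "glm_residuals.csv"
        import pandas as pd
        pd.DataFrame({"region_id": table.region_ids, "Y": table.Y, "E": table.E,
                      "mu_hat": glm.fitted, "ratio": ratios}).to_csv(residual_path, index=False)
        manifest["files"]["diagnostics"] = str(diag_path)
        manifest["files"]["glm_residuals"] = str(residual_path)
    except Exception as exc:
        raise RuntimeError(f"stage 'diagnostics' failed: {exc}") from exc

    for k, name in enumerate(config.strata):
        filt = STRATA[name]
        seed = _stratum_seed(config.seed, k)
        t0 = time.time()
        try:
            entry = _fit_stratum(name, filt, cases, pops, covs if config.use_covariates else None,
                                 graph, config, seed, outdir)
        except _EmptyStratum as empty:
            logger.warning("stratum %s skipped: %s", name, empty)
            manifest["skipped"][name] = str(empty)
            continue
        except Exception as exc:
            raise RuntimeError(f"stage 'fit:{name}' failed: {exc}") from exc
        entry["runtime_s"] = round(time.time() - t0, 2)
        entry["seed"] = seed
        manifest["strata"][name] = entry

    manifest["runtime_s"] = round(time.time() - t_start, 2)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    manifest["files"]["manifest"] = str(manifest_path)
    return manifest


class _EmptyStratum(Exception):
    pass


def subgraph(graph: graph_mod.RegionGraph, region_ids) -> graph_mod.RegionGraph:
    """Contiguity graph restricted to a subset of regions (edges within it)."""
    keep = set(region_ids)
    ids = graph.region_ids
    edges = [(ids[a], ids[b]) for a, b in zip(graph.edge_i, graph.edge_j)
             if ids[a] in keep and ids[b] in keep]
    return graph_mod.build_adjacency(edges, region_ids)


def _fit_stratum(name, filt, cases, pops, covs, graph, config: RunConfig,
                 seed: int, outdir: Path) -> dict:
    import pandas as pd

    table = cohort.expected_counts(cases, pops, graph.region_ids, **filt)
    if table.Y.sum() == 0:
        raise _EmptyStratum(f"no cases after applying filter {filt or 'overall'}")
    table, dropped = cohort.drop_zero_expected(table)
    sgraph = subgraph(graph, table.region_ids) if dropped else graph
    scovs = covs
    if covs is not None and dropped:
        keep = [graph.index_of(r) for r in table.region_ids]
        scovs = cov_mod.CovariateTable(
            table.region_ids, covs.sesi[keep], covs.pct_immigrant[keep],
            covs.pct_indigenous[keep])

    entry = {"files": {}, "dropped_regions": dropped}
    counts_path = outdir / f"counts_{name}.csv"
    table.to_frame().to_csv(counts_path, index=False)
    entry["files"]["counts"] = str(counts_path)

    model = SpatialCountModel(table, sgraph, covariates=scovs, priors=config.priors())
    res = model.fit(options=config.sampler_options(seed))
    entry["files"].update(res.save(outdir, stem=f"spatial_{name}"))
    irr = res.irr_summary()
    irr_path = outdir / f"irr_{name}.csv"
    irr.to_csv(irr_path, index=False)
    risk, counts_per_cat = res.region_risk_categories(
        scheme="fixed" if config.risk_breaks else "quintile", breaks=config.risk_breaks)
    risk_path = outdir / f"risk_{name}.csv"
    risk.to_csv(risk_path, index=False)
    entry["files"]["irr"] = str(irr_path)
    entry["files"]["risk"] = str(risk_path)
    entry["category_counts"] = [int(c) for c in counts_per_cat]
    entry["rhat"] = {p: round(float(v), 4) for p, v in res.rhat.items()}
    entry["converged"] = bool(res.converged)
    entry["acceptance"] = {p: round(float(v), 3) for p, v in res.draws.acceptance.items()}

    if config.periods:
        ptable = cohort.expected_counts_by_period(cases, pops, graph.region_ids,
                                                  rates="pooled", **filt)
        ptable, pdropped = cohort.drop_zero_expected(ptable)
        pgraph = subgraph(graph, ptable.region_ids) if pdropped else graph
        pcovs = scovs if not pdropped else None
        pmodel = SpatioTemporalCountModel(ptable, pgraph, covariates=pcovs,
                                          priors=config.priors())
        pres = pmodel.fit(options=config.sampler_options(_stratum_seed(seed, 1)))
        entry["files"].update({f"st_{k}": v for k, v in
                               pres.save(outdir, stem=f"spacetime_{name}").items()})
        prisk = pres.region_risk(temporal=True)
        prisk_path = outdir / f"risk_periods_{name}.csv"
        prisk.to_csv(prisk_path, index=False)
        entry["files"]["risk_periods"] = str(prisk_path)
        entry["rhat_spacetime"] = {p: round(float(v), 4) for p, v in pres.rhat.items()}
    return entry


def _versions() -> dict:
    import numpy
    import pandas
    import scipy

    from . import __version__
    return {"diseasemap": __version__, "numpy": numpy.__version__,
            "scipy": scipy.__version__, "pandas": pandas.__version__}
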