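"""Results object returned by the model classes' fit()."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import summaries
from .model import PosteriorDraws


class CountModelResults:
    """Posterior draws plus reporting helpers for a fitted count model.

    Attributes
    ----------
    model
        The model instance that produced the fit.
    draws
        Retained :class:`PosteriorDraws` across chains.
    rhat
        Split-chain potential scale reduction per scalar parameter
        (computed on construction when >= 2 chains were run).
    converged
        True when every monitored R-hat is <= 1.1; a False value is a
        warning, never an exception.
    """

    RHAT_LIMIT = 1.1

    def __init__(self, model, draws: PosteriorDraws):
        self.model = model
        self.draws = draws
        self.rhat = draws.rhat() if draws.n_chains >= 2 else {}
        self.converged = all(r <= self.RHAT_LIMIT for r in self.rhat.values())

    # -- point summaries ---------------------------------------------------

    def posterior_mean(self, name: str) -> float:
        return float(np.mean(self.draws.pooled(name)))

    def posterior_median(self, name: str) -> float:
        return float(np.median(self.draws.pooled(name)))

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        x = self.draws.pooled(name)
        a = 100 * (1 - level) / 2
        return float(np.percentile(x, a)), float(np.percentile(x, 100 - a))

    # -- report tables -----------------------------------------------------

    def irr_summary(self) -> pd.DataFrame:
        """Covariate incidence risk ratios with 95% credible intervals."""
        return summaries.irr_summary(self.draws)

    def region_risk(self, temporal: bool | None = None) -> pd.DataFrame:
        """Smoothed district-specific risk table (per period when temporal)."""
        if temporal is None:
            temporal = self.model.temporal
        return summaries.smoothed_region_risk(self.draws, temporal=temporal)

    def region_risk_categories(self, scheme="quintile", breaks=None):
        risk = summaries.smoothed_region_risk(self.draws, temporal=False)
        cats, counts = summaries.categorize_risk(risk["risk_median"].to_numpy(),
                                                 scheme=scheme, breaks=breaks)
        risk = risk.assign(category=cats)
        return risk, counts

    def summary(self) -> str:
        """Human-readable fit summary (statsmodels-style text table)."""
        lines = []
        mdl = "Spatio-temporal BYM Poisson model" if self.model.temporal \
            else "Spatial BYM Poisson model"
        opt = self.draws.options
        lines.append(mdl)
        lines.append("=" * 72)
        lines.append(f"Regions: {len(self.draws.region_ids):>5}    "
                     f"Chains: {self.draws.n_chains}  Iterations: {opt.n_iterations}  "
                     f"Burn-in: {opt.n_burnin}  Thin: {opt.thin}")
        if self.rhat:
            worst = max(self.rhat, key=self.rhat.get)
            lines.append(f"Convergence: max R-hat = {self.rhat[worst]:.3f} ({worst})"
                         + ("" if self.converged else "  ** exceeds 1.1 **"))
        lines.append("-" * 72)
        lines.append(f"{'parameter':<22}{'median':>10}{'mean':>10}{'2.5%':>10}{'97.5%':>10}")
        for name in self.draws.params:
            x = self.draws.pooled(name)
            lines.append(f"{name:<22}{np.median(x):>10.4f}{np.mean(x):>10.4f}"
                         f"{np.percentile(x, 2.5):>10.4f}{np.percentile(x, 97.5):>10.4f}")
        irr = self.irr_summary()
        if len(irr):
            lines.append("-" * 72)
            lines.append(f"{'covariate (IRR)':<22}{'IRR':>10}{'2.5%':>10}{'97.5%':>10}")
            for _, row in irr.iterrows():
                flag = "  *" if row["significant"] else ""
                lines.append(f"{row['covariate']:<22}{row['IRR']:>10.4f}"
                             f"{row['lower95']:>10.4f}{row['upper95']:>10.4f}{flag}")
        lines.append("=" * 72)
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, outdir, stem: str = "fit") -> dict:
        """Write draws (long CSV) and a JSON sidecar of metadata/diagnostics."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        draws_path = outdir / f"{stem}_draws.csv"
        self.draws.to_long_frame().to_csv(draws_path, index=False)
        opt = self.draws.options
        sidecar = {
            "seed": self.draws.seed,
            "n_chains": opt.n_chains, "n_iterations": opt.n_iterations,
            "n_burnin": opt.n_burnin, "thin": opt.thin,
            "acceptance": {k: float(v) for k, v in self.draws.acceptance.items()},
            "rhat": {k: float(v) for k, v in self.rhat.items()},
            "converged": bool(self.converged),
            "covariates": list(self.draws.covariate_names),
        }
        meta_path = outdir / f"{stem}_meta.json"
        meta_path.write_text(json.dumps(sidecar, indent=1))
        return {"draws": str(draws_path), "meta": str(meta_path)}
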