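"""Posterior reportables: IRR tables, smoothed risk surfaces, risk categories.

An IRR (incidence risk ratio) for a covariate is exp(beta), summarised by
the posterior median and equal-tailed 95% credible interval (medians are
equivariant under the exp transform).  Smoothed district risk is the
posterior of exp(u_i + eta_i), optionally times exp(gamma_t + phi_t) per
period; a region is flagged "elevated" when its whole 95% interval lies
above 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import PosteriorDraws


class SummaryInputError(ValueError):
    pass


def _exp_median_ci(log_draws_2d: np.ndarray):
    """exp of the (median, 2.5%, 97.5%) quantiles taken on the log scale."""
    med = np.exp(np.median(log_draws_2d, axis=0))
    lo = np.exp(np.percentile(log_draws_2d, 2.5, axis=0))
    hi = np.exp(np.percentile(log_draws_2d, 97.5, axis=0))
    return med, lo, hi


def irr_summary(draws: PosteriorDraws, covariate_names=None) -> pd.DataFrame:
    """Covariate IRR table: posterior median of exp(beta) with 95% interval."""
    names = tuple(covariate_names) if covariate_names else draws.covariate_names
    rows = []
    for name in names:
        key = f"beta:{name}"
        if key not in draws.params:
            raise SummaryInputError(f"no draws for covariate {name!r}")
        # quantiles taken on the log scale then exponentiated: quantiles are
        # equivariant under monotone transforms, so this is the IRR quantile
        beta = draws.pooled(key)
        med, lo, hi = np.exp([np.median(beta), np.percentile(beta, 2.5),
                              np.percentile(beta, 97.5)])
        rows.append({"covariate": name, "IRR": med, "lower95": lo, "upper95": hi,
                     "significant": bool(lo > 1.0 or hi < 1.0)})
    return pd.DataFrame(rows)


def smoothed_region_risk(draws: PosteriorDraws, temporal: bool = False) -> pd.DataFrame:
    """Posterior median and 95% interval of the smoothed district risk.

    Spatial: exp(u_i + eta_i) per region.  Temporal: exp(u_i + eta_i +
    gamma_t + phi_t) per region x period (long format).
    """
    for key in ("u", "eta"):
        if key not in draws.latent:
            raise SummaryInputError(f"missing latent draws {key!r}")
    u = draws.pooled("u")
    eta = draws.pooled("eta")
    spatial = u + eta  # (draws, n)
    if not temporal:
        med, lo, hi = _exp_median_ci(spatial)
        return pd.DataFrame({
            "region_id": draws.region_ids, "risk_median": med,
            "lower95": lo, "upper95": hi, "elevated": lo > 1.0})
    for key in ("gamma", "phi"):
        if key not in draws.latent:
            raise SummaryInputError(f"missing latent draws {key!r} (temporal model required)")
    tcomp = draws.pooled("gamma") + draws.pooled("phi")  # (draws, T)
    periods = draws.periods or tuple(range(1, tcomp.shape[1] + 1))
    frames = []
    for t, per in enumerate(periods):
        med, lo, hi = _exp_median_ci(spatial + tcomp[:, [t]])
        frames.append(pd.DataFrame({
            "region_id": draws.region_ids, "period": per, "risk_median": med,
            "lower95": lo, "upper95": hi, "elevated": lo > 1.0}))
    return pd.concat(frames, ignore_index=True)


def categorize_risk(values, scheme="quintile", breaks=None, n_categories: int = 5):
    """Assign each region a risk category; ties go to the lower category.

    Parameters
    ----------
    scheme
        "quintile" (default: quantile bins of the values) or "fixed"
        (explicit strictly increasing ``breaks``).

    Returns
    -------
    (categories, counts): 1-based integer category per region, and the
    per-category counts for map-legend rendering.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise SummaryInputError("risk values must be finite")
    if scheme == "fixed":
        if breaks is None:
            raise SummaryInputError("fixed scheme requires breaks")
        breaks = np.asarray(breaks, dtype=float)
        if np.any(np.diff(breaks) <= 0):
            raise SummaryInputError("fixed breaks must be strictly increasing")
        n_cat = len(breaks) + 1
    elif scheme == "quintile":
        if len(values) < n_categories:
            raise SummaryInputError("fewer regions than quantile categories")
        qs = np.arange(1, n_categories) / n_categories
        breaks = np.quantile(values, qs)
        n_cat = n_categories
    else:
        raise SummaryInputError(f"unknown categorisation scheme {scheme!r}")
    cats = 1 + (values[:, None] > breaks[None, :]).sum(axis=1)
    counts = np.bincount(cats, minlength=n_cat + 1)[1:n_cat + 1]
    return cats, counts
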