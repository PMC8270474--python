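"""Region-level covariates: factor-analysis SES index and population shares.

The socio-economic score index (SESI) is a single-factor summary of three
area indicators (median income, employment rate, education attainment).
Indicators are z-standardized, a one-factor loading vector is extracted
from their correlation matrix by the iterated principal-factor method,
and scores are formed by the regression method (weights R^{-1} Lambda on
the standardized indicators).  The sign is fixed so income loads
positively: a higher score always means better socio-economic status.
Because of the z-standardization the scores are invariant to affine
rescaling of any input indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class CovariateInputError(ValueError):
    pass


@dataclass
class CovariateTable:
    """Region-aligned covariate vectors (row order = graph region order)."""

    region_ids: tuple
    sesi: np.ndarray
    pct_immigrant: np.ndarray
    pct_indigenous: np.ndarray
    raw_indicators: pd.DataFrame | None = None
    centered: bool = False
    meta: dict = field(default_factory=dict)

    #: covariate column order used throughout the package
    names = ("sesi", "pct_immigrant", "pct_indigenous")

    def matrix(self) -> np.ndarray:
        """(n, 3) design matrix in the fixed column order ``names``."""
        return np.column_stack([self.sesi, self.pct_immigrant, self.pct_indigenous])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"region_id": self.region_ids, "sesi": self.sesi,
                             "pct_immigrant": self.pct_immigrant,
                             "pct_indigenous": self.pct_indigenous})

    def validate(self) -> None:
        n = len(self.region_ids)
        for name in self.names:
            v = getattr(self, name)
            if len(v) != n:
                raise CovariateInputError(f"{name} not aligned to region_ids")
            if not np.all(np.isfinite(v)):
                raise CovariateInputError(f"{name} contains non-finite values")
        if not self.centered:
            for name in ("pct_immigrant", "pct_indigenous"):
                v = getattr(self, name)
                if np.any(v < 0) or np.any(v > 100):
                    raise CovariateInputError(f"{name} outside [0, 100]")


def _iterated_principal_factor(R: np.ndarray, tol: float = 1e-8, max_iter: int = 500) -> np.ndarray:
    """One-factor loading vector from a correlation matrix.

    Starts from squared-multiple-correlation communalities and iterates
    the leading eigenpair of the reduced correlation matrix until the
    communalities stabilise.
    """
    p = R.shape[0]
    # SMC initial communalities; fall back to max |corr| when R is singular
    # (e.g. perfectly collinear indicators)
    if np.linalg.matrix_rank(R) == p:
        h2 = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    else:
        off = np.abs(R - np.eye(p))
        h2 = off.max(axis=0)
    for _ in range(max_iter):
        Rr = R.copy()
        Rr[np.diag_indices(p)] = h2
        vals, vecs = np.linalg.eigh(Rr)
        lam, v = vals[-1], vecs[:, -1]
        loadings = v * np.sqrt(max(lam, 0.0))
        h2_new = np.clip(loadings**2, 0.0, 1.0)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            break
        h2 = h2_new
    Rr = R.copy()
    Rr[np.diag_indices(p)] = h2
    vals, vecs = np.linalg.eigh(Rr)
    loadings = vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))
    return loadings


def compute_sesi(indicators: pd.DataFrame, rescale: tuple[float, float] | None = None) -> np.ndarray:
    """Single-factor SES scores from an income/employment/education table.

    Parameters
    ----------
    indicators
        DataFrame with columns ``income``, ``employment``, ``education``
        (one row per region, in region order).
    rescale
        Optional (lo, hi); when given, scores are affinely mapped so their
        minimum and maximum hit the endpoints exactly.
    """
    cols = ["income", "employment", "education"]
    missing = [c for c in cols if c not in indicators.columns]
    if missing:
        raise CovariateInputError(f"indicator table missing columns: {missing}")
    X = indicators[cols].to_numpy(dtype=float)
    if X.shape[0] < 4:
        raise CovariateInputError("need at least 4 regions for factor extraction")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        const = [c for c, s in zip(cols, sd) if s == 0]
        raise CovariateInputError(f"constant indicator column(s): {const}")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    loadings = _iterated_principal_factor(R)
    if loadings[cols.index("income")] < 0:
        loadings = -loadings
    weights, *_ = np.linalg.lstsq(R, loadings, rcond=None)  # regression-method scores
    scores = Z @ weights
    if np.corrcoef(scores, X[:, cols.index("income")])[0, 1] < 0:
        scores = -scores
    if rescale is not None:
        lo, hi = rescale
        if not hi > lo:
            raise CovariateInputError("rescale range must satisfy hi > lo")
        smin, smax = scores.min(), scores.max()
        scores = lo + (scores - smin) * (hi - lo) / (smax - smin)
    return scores


def assemble_covariates(sesi, pct_immigrant, pct_indigenous, region_ids,
                        input_region_ids=None, center: bool = False,
                        raw_indicators: pd.DataFrame | None = None) -> CovariateTable:
    """Align covariate vectors to graph region order into a CovariateTable.

    ``input_region_ids`` gives the region order of the input vectors when
    it differs from the target order; every region must be covered
    exactly once.
    """
    region_ids = tuple(region_ids)
    sesi = np.asarray(sesi, dtype=float)
    pct_imm = np.asarray(pct_immigrant, dtype=float)
    pct_ind = np.asarray(pct_indigenous, dtype=float)
    if input_region_ids is not None:
        input_region_ids = tuple(input_region_ids)
        missing = set(region_ids) - set(input_region_ids)
        if missing:
            raise CovariateInputError(f"covariates missing regions: {sorted(missing)}")
        if len(set(input_region_ids)) != len(input_region_ids):
            raise CovariateInputError("duplicate regions in covariate input")
        order = [input_region_ids.index(r) for r in region_ids]
        sesi, pct_imm, pct_ind = sesi[order], pct_imm[order], pct_ind[order]
        if raw_indicators is not None:
            raw_indicators = raw_indicators.iloc[order].reset_index(drop=True)
    table = CovariateTable(region_ids, sesi, pct_imm, pct_ind, raw_indicators=raw_indicators)
    table.validate()
    if center:
        means = {n: float(getattr(table, n).mean()) for n in table.names}
        for n in table.names:
            setattr(table, n, getattr(table, n) - means[n])
        table.centered = True
        table.meta["centering_means"] = means
    return table


def read_covariates_csv(path, region_ids) -> CovariateTable:
    """Read a ``region_id,sesi,pct_immigrant,pct_indigenous`` CSV, aligned to region order."""
    df = pd.read_csv(path, dtype={"region_id": str})
    return assemble_covariates(df["sesi"], df["pct_immigrant"], df["pct_indigenous"],
                               region_ids, input_region_ids=tuple(df["region_id"]))


def read_indicators_csv(path) -> pd.DataFrame:
    """Read a raw ``region_id,income,employment,education`` indicator CSV."""
    return pd.read_csv(path, dtype={"region_id": str})
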