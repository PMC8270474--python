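"""Line-list cases and stratum populations -> observed and expected counts.

Observed counts Y_i aggregate case records over sex j and age group k
within each region i.  Expected counts use *internal* indirect age-sex
standardization: reference rates y_jk / n_jk are computed from the pooled
analysed data itself and applied to each region's stratum populations,

    E_i = sum_jk (y_jk / n_jk) * n_ijk,

which guarantees sum_i E_i = sum_i Y_i.  Cases can be stratified by sex,
by topographical sub-site (cardia C160 vs non-cardia C161-C166/C168, with
C169 site-unspecified), and into multi-year diagnosis periods; for
period-stratified tables the reference rates are recomputed within each
period against the (assumed constant) population so conservation holds
per period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 12 age-group labels, youngest to oldest (k = 1..12).
AGE_GROUPS = (
    "<35", "35-39", "40-44", "45-49", "50-54", "55-59",
    "60-64", "65-69", "70-74", "75-79", "80-84", "85+",
)

SEXES = ("M", "F")

#: Valid ICD-O-3 stomach topography codes (C167 does not exist).
TOPOGRAPHY_CODES = ("C160", "C161", "C162", "C163", "C164", "C165", "C166", "C168", "C169")

#: Default 5-year diagnosis periods.
DEFAULT_PERIODS = ((1992, 1996), (1997, 2001), (2002, 2006), (2007, 2011), (2012, 2016))

_SUBSITE = {"C160": "cardia", "C169": "unspecified"}
_SUBSITE.update({c: "non_cardia" for c in TOPOGRAPHY_CODES if c not in _SUBSITE})


class CohortInputError(ValueError):
    """Malformed case/population input (bad code, unknown region, ...)."""


class DataConsistencyError(ValueError):
    """Cases observed in a stratum with zero recorded population."""


def classify_subsite(topography: str) -> str:
    """Map an ICD-O-3 stomach topography code to cardia / non_cardia / unspecified."""
    try:
        return _SUBSITE[topography]
    except KeyError:
        raise CohortInputError(f"invalid ICD-O-3 stomach topography code: {topography!r}") from None


def period_label(interval) -> str:
    return f"{interval[0]}-{interval[1]}"


def bin_period(year: int, period_scheme=DEFAULT_PERIODS) -> str:
    """Return the label of the diagnosis-period interval enclosing ``year``."""
    for lo, hi in period_scheme:
        if lo <= year <= hi:
            return period_label((lo, hi))
    raise CohortInputError(f"diagnosis year {year} falls outside all period intervals")


@dataclass
class CountTable:
    """Region-aligned observed (Y) and expected (E) counts.

    Y and E are 1-D ``(n,)`` arrays, or 2-D ``(n, T)`` when a period
    scheme was applied (columns follow ``periods``).  ``reference_rates``
    holds the internal y_jk/n_jk rates used to build E (per period for
    period tables).
    """

    region_ids: tuple
    Y: np.ndarray
    E: np.ndarray | None = None
    periods: tuple | None = None
    reference_rates: pd.DataFrame | None = None
    stratum: dict = field(default_factory=dict)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def to_frame(self) -> pd.DataFrame:
        if self.periods is None:
            df = pd.DataFrame({"region_id": self.region_ids, "Y": self.Y})
            if self.E is not None:
                df["E"] = self.E
            return df
        rows = []
        for t, per in enumerate(self.periods):
            for i, rid in enumerate(self.region_ids):
                row = {"region_id": rid, "period": per, "Y": self.Y[i, t]}
                if self.E is not None:
                    row["E"] = self.E[i, t]
                rows.append(row)
        return pd.DataFrame(rows)

    def validate(self) -> None:
        Y = np.asarray(self.Y)
        if Y.shape[0] != self.n_regions:
            raise CohortInputError("Y not aligned to region_ids")
        if np.any(Y < 0) or not np.allclose(Y, np.round(Y)):
            raise CohortInputError("Y must contain non-negative integers")
        if self.E is not None:
            E = np.asarray(self.E)
            if E.shape != Y.shape:
                raise CohortInputError("E shape differs from Y")
            if not np.all(np.isfinite(E)) or np.any(E < 0):
                raise CohortInputError("E must be finite and non-negative")


def _check_cases(cases: pd.DataFrame, region_ids) -> pd.DataFrame:
    required = {"region_id", "sex", "age_group", "year", "topography"}
    missing = required - set(cases.columns)
    if missing:
        raise CohortInputError(f"case table missing columns: {sorted(missing)}")
    bad_age = set(cases["age_group"]) - set(AGE_GROUPS)
    if bad_age:
        raise CohortInputError(f"unknown age-group labels: {sorted(bad_age)}")
    bad_sex = set(cases["sex"]) - set(SEXES)
    if bad_sex:
        raise CohortInputError(f"unknown sex codes: {sorted(bad_sex)}")
    bad_topo = set(cases["topography"]) - set(TOPOGRAPHY_CODES)
    if bad_topo:
        raise CohortInputError(f"invalid topography codes: {sorted(bad_topo)}")
    unknown = set(cases["region_id"]) - set(region_ids)
    if unknown:
        raise CohortInputError(f"case records reference unknown regions: {sorted(unknown)[:5]}")
    return cases


def _apply_filters(cases: pd.DataFrame, sex=None, subsite=None) -> pd.DataFrame:
    if sex is not None:
        if sex not in SEXES:
            raise CohortInputError(f"sex filter must be one of {SEXES}, got {sex!r}")
        cases = cases[cases["sex"] == sex]
    if subsite is not None:
        if subsite not in ("cardia", "non_cardia", "unspecified"):
            raise CohortInputError(f"unknown sub-site filter {subsite!r}")
        cases = cases[cases["topography"].map(classify_subsite) == subsite]
    return cases


def aggregate_counts(cases: pd.DataFrame, region_ids, sex=None, subsite=None,
                     period_scheme=None) -> CountTable:
    """Aggregate filtered line-list records into per-region observed counts Y.

    Regions with no matching records get Y = 0.  With a period scheme the
    result is a (regions x periods) matrix whose region-wise sum equals
    the unstratified counts of the same filter.
    """
    region_ids = tuple(region_ids)
    cases = _apply_filters(_check_cases(cases, region_ids), sex, subsite)
    idx = {r: k for k, r in enumerate(region_ids)}
    pos = cases["region_id"].map(idx).to_numpy(dtype=int) if len(cases) else np.zeros(0, int)
    meta = {"sex": sex, "subsite": subsite}
    if period_scheme is None:
        Y = np.bincount(pos, minlength=len(region_ids)).astype(int)
        return CountTable(region_ids, Y, stratum=meta)
    labels = tuple(period_label(p) for p in period_scheme)
    tpos = cases["year"].map(lambda y: labels.index(bin_period(y, period_scheme))).to_numpy(dtype=int) if len(cases) else np.zeros(0, int)
    Y = np.zeros((len(region_ids), len(labels)), dtype=int)
    np.add.at(Y, (pos, tpos), 1)
    return CountTable(region_ids, Y, periods=labels, stratum=meta)


def _check_populations(populations: pd.DataFrame, region_ids) -> pd.DataFrame:
    required = {"region_id", "sex", "age_group", "count"}
    missing = required - set(populations.columns)
    if missing:
        raise CohortInputError(f"population table missing columns: {sorted(missing)}")
    if (populations["count"] < 0).any():
        raise CohortInputError("negative stratum population")
    dup = populations.duplicated(subset=["region_id", "sex", "age_group"])
    if dup.any():
        raise CohortInputError("duplicate (region, sex, age_group) population rows")
    unknown = set(populations["region_id"]) - set(region_ids)
    if unknown:
        raise CohortInputError(f"population rows reference unknown regions: {sorted(unknown)[:5]}")
    return populations


def _standardize(case_subset: pd.DataFrame, populations: pd.DataFrame, region_ids) -> tuple[np.ndarray, pd.DataFrame]:
    """Internal indirect standardization for one (filter, period) slice.

    Returns (E per region, reference-rate table).  Strata with zero
    population and zero cases contribute nothing (0/0 -> 0); zero
    population with positive cases is a data-consistency error.
    """
    y_jk = (case_subset.groupby(["sex", "age_group"], observed=True).size()
            .rename("y").reset_index())
    n_jk = (populations.groupby(["sex", "age_group"], observed=True)["count"].sum()
            .rename("n").reset_index())
    rates = n_jk.merge(y_jk, on=["sex", "age_group"], how="outer").fillna({"y": 0, "n": 0})
    bad = rates[(rates["y"] > 0) & (rates["n"] == 0)]
    if len(bad):
        strata = list(zip(bad["sex"], bad["age_group"]))
        raise DataConsistencyError(f"cases observed in strata with zero population: {strata}")
    with np.errstate(invalid="ignore", divide="ignore"):
        rates["rate"] = np.where(rates["n"] > 0, rates["y"] / rates["n"], 0.0)
    pop = populations.merge(rates[["sex", "age_group", "rate"]], on=["sex", "age_group"], how="left")
    contrib = pop["count"] * pop["rate"]
    e_by_region = contrib.groupby(pop["region_id"]).sum()
    E = np.array([e_by_region.get(r, 0.0) for r in region_ids])
    return E, rates[["sex", "age_group", "y", "n", "rate"]]


def expected_counts(cases: pd.DataFrame, populations: pd.DataFrame, region_ids,
                    sex=None, subsite=None) -> CountTable:
    """Observed and internally standardized expected counts, one row per region."""
    region_ids = tuple(region_ids)
    cases = _apply_filters(_check_cases(cases, region_ids), sex, subsite)
    populations = _check_populations(populations, region_ids)
    if sex is not None:
        populations = populations[populations["sex"] == sex]
    table = aggregate_counts(cases, region_ids)
    E, rates = _standardize(cases, populations, region_ids)
    return CountTable(region_ids, table.Y, E=E, reference_rates=rates,
                      stratum={"sex": sex, "subsite": subsite})


def expected_counts_by_period(cases: pd.DataFrame, populations: pd.DataFrame, region_ids,
                              period_scheme=DEFAULT_PERIODS, sex=None, subsite=None,
                              rates: str = "within") -> CountTable:
    """Per-period observed and expected counts.

    Two standardization modes, differing in what the expected counts
    condition away:

    ``rates="within"`` (default)
        Reference rates recomputed within each period from that period's
        case totals against the same (assumed constant) population, so
        sum_i E_it = sum_i Y_it holds for every period t.  Region-period
        SIRs then measure purely *spatial* contrasts within each period:
        any province-wide temporal trend is absorbed into E.

    ``rates="pooled"``
        Reference rates from the case totals pooled over all periods (the
        same y_jk/n_jk as the unstratified table), with each region's
        total expectation spread over periods in proportion to
        person-time (period length).  Conservation then holds globally
        but not per period — deliberately, so that province-wide temporal
        trends remain in the data and the temporal effects of a
        spatio-temporal model can estimate them.
    """
    region_ids = tuple(region_ids)
    cases = _apply_filters(_check_cases(cases, region_ids), sex, subsite)
    populations = _check_populations(populations, region_ids)
    if sex is not None:
        populations = populations[populations["sex"] == sex]
    table = aggregate_counts(cases, region_ids, period_scheme=period_scheme)
    meta = {"sex": sex, "subsite": subsite, "rates": rates,
            "period_scheme": tuple(map(tuple, period_scheme))}
    if rates == "within":
        E = np.zeros_like(table.Y, dtype=float)
        rate_frames = []
        for t, per in enumerate(table.periods):
            sub = cases[cases["year"].map(lambda y: bin_period(y, period_scheme)) == per] if len(cases) else cases
            E[:, t], rtab = _standardize(sub, populations, region_ids)
            rate_frames.append(rtab.assign(period=per))
        ref = pd.concat(rate_frames, ignore_index=True)
    elif rates == "pooled":
        e_total, ref = _standardize(cases, populations, region_ids)
        years = np.array([hi - lo + 1 for lo, hi in period_scheme], dtype=float)
        E = e_total[:, None] * (years / years.sum())[None, :]
    else:
        raise CohortInputError(f"rates must be 'within' or 'pooled', got {rates!r}")
    return CountTable(region_ids, table.Y, E=E, periods=table.periods,
                      reference_rates=ref, stratum=meta)


def drop_zero_expected(table: CountTable) -> tuple[CountTable, list]:
    """Remove regions whose expected count is identically zero.

    The Poisson mean lambda_i * E_i is 0 for such regions regardless of
    the model, so they carry no information; they are dropped with a
    logged warning before fitting.
    """
    E = np.asarray(table.E)
    tot = E if E.ndim == 1 else E.sum(axis=1)
    keep = tot > 0
    dropped = [r for r, k in zip(table.region_ids, keep) if not k]
    if dropped:
        logger.warning("dropping %d regions with zero expected count: %s", len(dropped), dropped[:10])
    sub = CountTable(
        tuple(r for r, k in zip(table.region_ids, keep) if k),
        np.asarray(table.Y)[keep], E=E[keep], periods=table.periods,
        reference_rates=table.reference_rates, stratum=dict(table.stratum),
    )
    return sub, dropped


def read_cases_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"region_id": str, "sex": str, "age_group": str,
                                  "topography": str})
    df["year"] = df["year"].astype(int)
    return df


def read_populations_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"region_id": str, "sex": str, "age_group": str})
    df["count"] = df["count"].astype(float)
    return df
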