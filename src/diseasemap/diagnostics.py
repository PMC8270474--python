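"""Pre-model spatial-dependency diagnostics.

Workflow: fit a non-spatial Poisson GLM with a log E offset, map the
per-region unexplained variation Y_i / mu_hat_i, then confirm spatial
clustering of those ratios with the global Moran's I statistic under a
permutation null.  Moran's I uses the raw binary contiguity weights with
S0 normalisation,

    I = (n / S0) * sum_ij w_ij (y_i - ybar)(y_j - ybar) / sum_i (y_i - ybar)^2,

and the permutation p-value is one-sided upper (positive autocorrelation,
i.e. clustering, is the alternative of interest) with the +1 correction
so p is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import RegionGraph


class DiagnosticsError(ValueError):
    pass


@dataclass
class GLMFit:
    """Maximum-likelihood fit of log mu_i = log E_i + a + b.x_i."""

    coefficients: np.ndarray  # intercept first
    fitted: np.ndarray        # mu_hat per region
    loglik: float
    n_iterations: int
    converged: bool
    loglik_trace: np.ndarray


@dataclass
class MoranResult:
    i_value: float
    n_regions: int
    n_permutations: int
    p_value: float
    seed: int

    def to_dict(self) -> dict:
        return {"I": self.i_value, "p_value": self.p_value,
                "n_regions": self.n_regions,
                "n_permutations": self.n_permutations, "seed": self.seed}


def _poisson_loglik(Y, mu):
    # constant log(Y!) omitted: only differences matter for convergence
    return float(np.sum(Y * np.log(mu) - mu))


def fit_poisson_glm(Y, E, X=None, tol: float = 1e-10, max_iter: int = 100) -> GLMFit:
    """Fit the log-linear Poisson model by iteratively reweighted least squares.

    Parameters
    ----------
    Y, E
        Observed and expected counts per region; E must be positive.
    X
        Optional (n, p) covariate matrix (no intercept column; one is
        added internally).  Must have full column rank.
    """
    Y = np.asarray(Y, dtype=float)
    E = np.asarray(E, dtype=float)
    if np.any(E <= 0):
        raise DiagnosticsError("all expected counts must be positive for GLM fitting")
    n = len(Y)
    if X is None:
        D = np.ones((n, 1))
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != n:
            X = X.T
        D = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise DiagnosticsError("design matrix is rank deficient")
    offset = np.log(E)
    # start at the intercept-only MLE
    beta = np.zeros(D.shape[1])
    beta[0] = np.log(max(Y.sum(), 0.5) / E.sum())
    eta = offset + D @ beta
    mu = np.exp(eta)
    ll = _poisson_loglik(Y, mu)
    trace = [ll]
    converged = False
    for it in range(1, max_iter + 1):
        # IRLS working response and weights for the log link
        z = (eta - offset) + (Y - mu) / mu
        W = mu
        WD = D * W[:, None]
        beta = np.linalg.solve(D.T @ WD, WD.T @ z)
        eta = offset + D @ beta
        mu = np.exp(eta)
        ll_new = _poisson_loglik(Y, mu)
        trace.append(ll_new)
        if abs(ll_new - ll) <= tol * (abs(ll) + 1e-12):
            converged = True
            ll = ll_new
            break
        ll = ll_new
    if not converged:
        raise DiagnosticsError(
            f"IRLS did not converge in {max_iter} iterations; log-likelihood trace: {trace}")
    return GLMFit(beta, mu, ll, it, converged, np.asarray(trace))


def residual_risk_ratio(Y, fit: GLMFit) -> np.ndarray:
    """Per-region unexplained variation: observed over covariate-adjusted expectation."""
    Y = np.asarray(Y, dtype=float)
    if len(Y) != len(fit.fitted):
        raise DiagnosticsError("Y length does not match fitted values")
    return Y / fit.fitted


def morans_i(values, graph: RegionGraph) -> float:
    """Global Moran's I with binary contiguity weights and S0 normalisation."""
    y = np.asarray(values, dtype=float)
    n = graph.n_regions
    if len(y) != n:
        raise DiagnosticsError("values not aligned to graph regions")
    if n < 2:
        raise DiagnosticsError("Moran's I needs at least 2 regions")
    if graph.n_edges == 0:
        raise DiagnosticsError("Moran's I undefined on an edgeless graph")
    z = y - y.mean()
    denom = np.sum(z**2)
    if denom == 0:
        raise DiagnosticsError("Moran's I undefined for zero-variance values")
    num = 2.0 * np.sum(z[graph.edge_i] * z[graph.edge_j])  # both (i,j) and (j,i)
    return float((n / graph.s0) * num / denom)


def morans_i_permutation_test(values, graph: RegionGraph, n_permutations: int = 999,
                              seed: int = 0) -> MoranResult:
    """Permutation test of Moran's I against the exchangeability null.

    Value-to-region assignments are permuted uniformly; the p-value is
    (1 + #{I_perm >= I_obs}) / (1 + n_permutations), one-sided upper.
    """
    if n_permutations < 99:
        raise DiagnosticsError("use at least 99 permutations")
    y = np.asarray(values, dtype=float)
    i_obs = morans_i(y, graph)
    rng = np.random.default_rng(seed)
    n = graph.n_regions
    z = y - y.mean()
    denom = np.sum(z**2)
    perm = np.empty((n_permutations, n))
    for b in range(n_permutations):
        perm[b] = z[rng.permutation(n)]
    num = 2.0 * np.sum(perm[:, graph.edge_i] * perm[:, graph.edge_j], axis=1)
    i_perm = (n / graph.s0) * num / denom
    p = (1.0 + np.sum(i_perm >= i_obs)) / (1.0 + n_permutations)
    return MoranResult(i_obs, n, n_permutations, float(p), seed)
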