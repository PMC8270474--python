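"""Hierarchical Bayesian Poisson models for area-level incidence counts.

The spatial model is the BYM convolution: observed counts are
Y_i ~ Poisson(lambda_i E_i) with

    log(lambda_i) = alpha + beta.x_i + u_i + eta_i,

where u_i ~ N(0, sigma2_u) is unstructured heterogeneity and eta is an
intrinsic CAR (ICAR) field — each eta_i is conditionally Gaussian around
the mean of its neighbors with variance sigma2_eta / degree(i).  The
spatio-temporal model adds an exchangeable period effect gamma_t and a
first-order random-walk effect phi_t, additively (no space-time
interaction):

    log(lambda_it) = alpha + beta.x_i + u_i + eta_i + gamma_t + phi_t.

Priors: alpha improper flat, beta ~ N(0, 1000), and Gamma(0.1, 0.01)
hyperpriors on every precision tau = 1/sigma2.  Inference is
Metropolis-within-Gibbs: vectorised single-site random-walk Metropolis
for alpha, beta and the latent fields (fields grouped by a proper graph
colouring so conditionally independent sites update in parallel),
conjugate Gamma draws for the precisions, and sum-to-zero recentring of
eta and phi each sweep with the deducted means absorbed into alpha (both
transforms leave the posterior invariant: the ICAR and RW(1) priors are
shift-free and alpha's prior is flat).  Proposal scales adapt toward 0.44
acceptance during burn-in only and are frozen afterwards, preserving
detailed balance for the retained draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .cohort import CountTable
from .covariates import CovariateTable
from .graph import RegionGraph
from .simulate import icar_basis, make_lattice


class ModelInputError(ValueError):
    pass


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# specification containers


@dataclass
class PriorSpec:
    """Priors: flat intercept, Gaussian slopes, Gamma precisions."""

    beta_mean: float = 0.0
    beta_var: float = 1000.0
    precision_shape: float = 0.1
    precision_rate: float = 0.01

    def __post_init__(self):
        if self.beta_var <= 0:
            raise ConfigError("beta_var must be positive")
        if self.precision_shape <= 0 or self.precision_rate <= 0:
            raise ConfigError("Gamma hyperprior parameters must be positive")


@dataclass
class SamplerOptions:
    """MCMC budget and adaptation settings."""

    n_chains: int = 4
    n_iterations: int = 30_000
    n_burnin: int = 10_000
    thin: int = 10
    seed: int = 0
    target_accept: float = 0.44
    adapt_every: int = 50
    fixed_precisions: dict | None = None  # e.g. {"tau_u": 1.0, "tau_eta": 1.0}

    def __post_init__(self):
        if self.n_chains < 1:
            raise ConfigError("need at least one chain")
        if not 0 <= self.n_burnin < self.n_iterations:
            raise ConfigError("require 0 <= n_burnin < n_iterations")
        if self.thin < 1:
            raise ConfigError("thinning must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.n_burnin) // self.thin


# ---------------------------------------------------------------------------
# structural primitives (exposed for direct use and testing)


def icar_conditional(eta, graph: RegionGraph, i: int, sigma2_eta: float):
    """Full conditional of one ICAR site: N(neighbor mean, sigma2_eta / degree)."""
    nbrs = graph.neighbor_sets()[i]
    if not nbrs:
        raise ModelInputError(
            f"region {graph.region_ids[i]!r} has no neighbors; its CAR conditional "
            "is undefined (islands are pinned to 0 in the sampler)")
    nb = np.array(sorted(nbrs))
    return float(np.mean(np.asarray(eta)[nb])), sigma2_eta / len(nb)


def icar_quadratic_form(eta, graph: RegionGraph) -> float:
    """Pairwise-difference form sum_{i~j, i<j} (eta_i - eta_j)^2."""
    eta = np.asarray(eta, dtype=float)
    d = eta[graph.edge_i] - eta[graph.edge_j]
    return float(np.sum(d * d))


def rw1_conditional(phi, t: int, sigma2_phi: float):
    """Full conditional of a first-order random walk at 0-based time t.

    Endpoints: N(phi of the single temporal neighbor, sigma2_phi);
    interior: N(mean of the two neighbors, sigma2_phi / 2).
    """
    phi = np.asarray(phi, dtype=float)
    T = len(phi)
    if T < 2:
        raise ModelInputError("RW(1) needs at least 2 periods")
    if not 0 <= t < T:
        raise ModelInputError(f"time index {t} outside 0..{T - 1}")
    if t == 0:
        return float(phi[1]), sigma2_phi
    if t == T - 1:
        return float(phi[T - 2]), sigma2_phi
    return float((phi[t - 1] + phi[t + 1]) / 2.0), sigma2_phi / 2.0


def rw1_quadratic_form(phi) -> float:
    phi = np.asarray(phi, dtype=float)
    return float(np.sum(np.diff(phi) ** 2))


def precision_posterior(values, structure: str, prior: PriorSpec,
                        graph: RegionGraph | None = None) -> tuple[float, float]:
    """(shape, rate) of the conjugate Gamma full conditional for a precision.

    Rank r of the structure's improper Gaussian: n for iid, n - c for an
    ICAR field on a graph with c connected components, T - 1 for RW(1).
    """
    values = np.asarray(values, dtype=float)
    a, b = prior.precision_shape, prior.precision_rate
    if structure == "iid":
        q = float(np.sum(values**2))
        r = len(values)
    elif structure == "icar":
        if graph is None:
            raise ConfigError("icar precision update requires the region graph")
        q = icar_quadratic_form(values, graph)
        r = graph.n_regions - graph.n_components
    elif structure == "rw1":
        q = rw1_quadratic_form(values)
        r = len(values) - 1
    else:
        raise ConfigError(f"unknown structure {structure!r}")
    return a + r / 2.0, b + q / 2.0


def update_precision(values, structure: str, prior: PriorSpec, rng,
                     graph: RegionGraph | None = None) -> float:
    """Draw a precision from its conjugate Gamma full conditional."""
    shape, rate = precision_posterior(values, structure, prior, graph)
    return float(rng.gamma(shape, 1.0 / rate))


def gelman_rubin(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor R-hat.

    ``chains`` has shape (n_chains, n_draws); each chain is split in half
    before the classical between/within variance comparison.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ModelInputError("R-hat needs at least 2 chains of draws")
    if x.shape[1] < 10:
        raise ModelInputError("R-hat needs at least 10 draws per chain")
    half = x.shape[1] // 2
    splits = np.vstack([x[:, :half], x[:, half:2 * half]])
    m, n = splits.shape
    means = splits.mean(axis=1)
    W = splits.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


# ---------------------------------------------------------------------------
# posterior draw container


@dataclass
class PosteriorDraws:
    """Retained MCMC draws across chains, with sampler metadata."""

    params: dict           # name -> (n_chains, n_draws)
    latent: dict           # name -> (n_chains, n_draws, dim)
    acceptance: dict       # block name -> mean acceptance rate
    seed: int
    options: SamplerOptions
    region_ids: tuple
    periods: tuple | None
    covariate_names: tuple

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated: (chains*draws,) or (chains*draws, dim)."""
        if name in self.params:
            return self.params[name].reshape(-1)
        if name in self.latent:
            arr = self.latent[name]
            return arr.reshape(-1, arr.shape[-1])
        raise KeyError(name)

    def rhat(self) -> dict:
        return {name: gelman_rubin(arr) for name, arr in self.params.items()}

    def to_long_frame(self) -> pd.DataFrame:
        """Long table chain,iteration,parameter,value (scalar parameters only)."""
        rows = []
        for name, arr in self.params.items():
            for c in range(arr.shape[0]):
                rows.append(pd.DataFrame({
                    "chain": c, "iteration": np.arange(arr.shape[1]),
                    "parameter": name, "value": arr[c]}))
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# the sampler


class _Structure:
    """Precomputed graph/period structure shared by all chains."""

    def __init__(self, graph: RegionGraph, T: int):
        self.graph = graph
        self.n = graph.n_regions
        self.T = T
        deg = graph.degrees
        self.degrees = deg.astype(float)
        self.islands = np.flatnonzero(deg == 0)
        self.non_islands = np.flatnonzero(deg > 0)
        self.n_components = graph.n_components
        self.eta_rank = self.n - self.n_components
        # adjacency as neighbor-sum operator, pre-sliced per colour class
        self.W = graph.adjacency_matrix()
        colors = graph.greedy_coloring()
        classes = [np.flatnonzero((colors == c) & (deg > 0))
                   for c in range(colors.max() + 1)]
        self.eta_classes = [(cls, self.W[cls].tocsr(), self.degrees[cls])
                            for cls in classes if len(cls)]
        if T > 1:
            path = make_lattice(1, T)
            self.phi_deg = path.degrees.astype(float)
            pW = path.adjacency_matrix()
            self.phi_classes = [(cls, pW[cls].tocsr(), self.phi_deg[cls])
                                for cls in (np.arange(0, T, 2), np.arange(1, T, 2))]


class _ChainState:
    __slots__ = ("alpha", "beta", "u", "eta", "gamma", "phi",
                 "tau_u", "tau_eta", "tau_gamma", "tau_phi", "base")

    def copy_record(self):
        return dict(alpha=self.alpha, beta=self.beta.copy(), u=self.u.copy(),
                    eta=self.eta.copy(), gamma=self.gamma.copy(), phi=self.phi.copy(),
                    tau_u=self.tau_u, tau_eta=self.tau_eta,
                    tau_gamma=self.tau_gamma, tau_phi=self.tau_phi)


class _GibbsSampler:
    """Metropolis-within-Gibbs for the (spatio-temporal) BYM model."""

    def __init__(self, Y: np.ndarray, E: np.ndarray, X: np.ndarray | None,
                 struct: _Structure, priors: PriorSpec, options: SamplerOptions):
        self.Y = Y.astype(float)          # (n, T)
        self.E = E.astype(float)          # (n, T)
        self.p = 0 if X is None else X.shape[1]
        # covariates are centred internally for sampling (decorrelates the
        # intercept from the slopes); the recorded intercept is shifted back
        # to the original covariate scale, so beta is unaffected
        if self.p:
            self.xmean = X.mean(axis=0)
            self.X = X - self.xmean
        else:
            self.xmean = None
            self.X = None
        self.s = struct
        self.priors = priors
        self.opt = options
        self.temporal = struct.T > 1
        self.A = self.Y.sum(axis=1)       # per-region case totals
        self.C = self.Y.sum(axis=0)       # per-period case totals
        self.S_Y = float(self.Y.sum())
        if self.S_Y <= 0:
            raise ModelInputError("total observed count is zero; the flat intercept "
                                  "prior yields an improper posterior")
        if self.p:
            self.SAx = self.X.T @ self.A  # sum_i A_i x_ij
        fixed = options.fixed_precisions or {}
        allowed = {"tau_u", "tau_eta", "tau_gamma", "tau_phi"}
        unknown = set(fixed) - allowed
        if unknown:
            raise ConfigError(f"unknown fixed precisions: {sorted(unknown)}")
        self.fixed = {k: float(v) for k, v in fixed.items()}

    # -- initialisation ----------------------------------------------------

    def init_state(self, rng) -> _ChainState:
        s = _ChainState()
        n, T = self.s.n, self.s.T
        mle = np.log(self.S_Y / self.E.sum())
        s.alpha = mle + rng.normal(0.0, 0.3)
        s.beta = np.zeros(self.p)
        if self.p:
            sd = self.X.std(axis=0)
            s.beta = rng.normal(0.0, 0.05 / np.maximum(sd, 1e-8))
        s.u = rng.normal(0.0, 0.1, size=n)
        s.eta = rng.normal(0.0, 0.1, size=n)
        s.eta[self.s.islands] = 0.0
        ni = self.s.non_islands
        if len(ni):
            s.eta[ni] -= s.eta[ni].mean()
        s.gamma = np.zeros(T)
        s.phi = np.zeros(T)
        if self.temporal:
            s.gamma = rng.normal(0.0, 0.05, size=T)
            s.phi = rng.normal(0.0, 0.05, size=T)
            s.phi -= s.phi.mean()
        for name in ("tau_u", "tau_eta", "tau_gamma", "tau_phi"):
            setattr(s, name, self.fixed.get(name, float(np.exp(rng.uniform(np.log(0.5), np.log(20.0))))))
        xb = self.X @ s.beta if self.p else 0.0
        s.base = s.alpha + xb + s.u + s.eta
        return s

    def init_scales(self):
        n, T = self.s.n, self.s.T
        ls = {"u": np.full(n, np.log(0.3)), "eta": np.full(n, np.log(0.3)),
              "alpha": np.log(0.1), "swap_u": np.log(0.1)}
        if self.p:
            ls["beta"] = np.log(0.1 / np.maximum(self.X.std(axis=0), 1e-8))
        if self.temporal:
            ls["gamma"] = np.full(T, np.log(0.2))
            ls["phi"] = np.full(T, np.log(0.2))
            ls["swap_gamma"] = np.log(0.2)
        return ls

    # -- one sweep ---------------------------------------------------------

    def sweep(self, st: _ChainState, rng, ls, acc):
        s = self.s
        tp = st.gamma + st.phi if self.temporal else np.zeros(1)
        B = self.E @ np.exp(tp) if self.temporal else self.E[:, 0]  # (n,)

        # unstructured spatial effects u (conditionally independent given rest)
        lam = B * np.exp(st.base)
        du = rng.normal(size=s.n) * np.exp(ls["u"])
        dll = self.A * du - lam * np.expm1(du)
        dlp = -0.5 * st.tau_u * (2 * st.u * du + du * du)
        ok = np.log(rng.random(s.n)) < dll + dlp
        st.u[ok] += du[ok]
        st.base[ok] += du[ok]
        acc["u"] += ok

        # structured spatial effects eta, one colour class at a time
        for cls, Wc, deg_c in s.eta_classes:
            lam_c = B[cls] * np.exp(st.base[cls])
            de = rng.normal(size=len(cls)) * np.exp(ls["eta"][cls])
            nsum = Wc @ st.eta
            dll = self.A[cls] * de - lam_c * np.expm1(de)
            dlp = -0.5 * st.tau_eta * (
                2 * de * (deg_c * st.eta[cls] - nsum) + deg_c * de * de)
            ok = np.log(rng.random(len(cls))) < dll + dlp
            idx = cls[ok]
            st.eta[idx] += de[ok]
            st.base[idx] += de[ok]
            acc["eta"][cls] += ok

        # recentre eta; absorb the mean into alpha (posterior-invariant)
        ni = s.non_islands
        if len(ni):
            m = st.eta[ni].mean()
            st.eta[ni] -= m
            st.alpha += m
            if len(s.islands):
                st.base[s.islands] += m

        # intercept (flat prior)
        tot = float(B @ np.exp(st.base))
        da = rng.normal() * np.exp(ls["alpha"])
        if np.log(rng.random()) < self.S_Y * da - tot * np.expm1(da):
            st.alpha += da
            st.base += da
            acc["alpha"] += 1

        # level-swap move: shift alpha by d and every u_i by -d.  The
        # likelihood is invariant (alpha + u_i unchanged) and alpha's prior
        # is flat, so only the iid u prior enters the ratio; this
        # decorrelates the intercept from the u-field level.
        d = rng.normal() * np.exp(ls["swap_u"])
        dlp = -0.5 * st.tau_u * (-2 * d * st.u.sum() + s.n * d * d)
        if np.log(rng.random()) < dlp:
            st.alpha += d
            st.u -= d
            acc["swap_u"] += 1

        # slopes
        for j in range(self.p):
            xj = self.X[:, j]
            db = rng.normal() * np.exp(ls["beta"][j])
            cur = B * np.exp(st.base)
            dll = self.SAx[j] * db - float(cur @ np.expm1(xj * db))
            bj = st.beta[j]
            dlp = -0.5 / self.priors.beta_var * (
                (bj + db - self.priors.beta_mean) ** 2 - (bj - self.priors.beta_mean) ** 2)
            if np.log(rng.random()) < dll + dlp:
                st.beta[j] += db
                st.base += xj * db
                acc["beta"][j] += 1

        if self.temporal:
            D = self.E.T @ np.exp(st.base)  # (T,)

            # exchangeable period effects gamma (conditionally independent)
            lam_t = D * np.exp(st.gamma + st.phi)
            dg = rng.normal(size=s.T) * np.exp(ls["gamma"])
            dll = self.C * dg - lam_t * np.expm1(dg)
            dlp = -0.5 * st.tau_gamma * (2 * st.gamma * dg + dg * dg)
            ok = np.log(rng.random(s.T)) < dll + dlp
            st.gamma[ok] += dg[ok]
            acc["gamma"] += ok

            # RW(1) effects phi, even/odd classes
            for cls, Wc, deg_c in s.phi_classes:
                lam_c = D[cls] * np.exp(st.gamma[cls] + st.phi[cls])
                dp = rng.normal(size=len(cls)) * np.exp(ls["phi"][cls])
                nsum = Wc @ st.phi
                dll = self.C[cls] * dp - lam_c * np.expm1(dp)
                dlp = -0.5 * st.tau_phi * (
                    2 * dp * (deg_c * st.phi[cls] - nsum) + deg_c * dp * dp)
                ok = np.log(rng.random(len(cls))) < dll + dlp
                idx = cls[ok]
                st.phi[idx] += dp[ok]
                acc["phi"][cls] += ok

            # recentre phi into alpha
            m = st.phi.mean()
            st.phi -= m
            st.alpha += m
            st.base += m

            # level swap between alpha and the exchangeable gamma field
            d = rng.normal() * np.exp(ls["swap_gamma"])
            dlp = -0.5 * st.tau_gamma * (-2 * d * st.gamma.sum() + s.T * d * d)
            if np.log(rng.random()) < dlp:
                st.alpha += d
                st.base += d
                st.gamma -= d
                acc["swap_gamma"] += 1

        # conjugate precision updates (inline closed-form Gamma draws)
        a, b = self.priors.precision_shape, self.priors.precision_rate
        if "tau_u" not in self.fixed:
            st.tau_u = rng.gamma(a + s.n / 2.0, 1.0 / (b + 0.5 * float(st.u @ st.u)))
        if "tau_eta" not in self.fixed:
            deta = st.eta[s.graph.edge_i] - st.eta[s.graph.edge_j]
            st.tau_eta = rng.gamma(a + s.eta_rank / 2.0,
                                   1.0 / (b + 0.5 * float(deta @ deta)))
        if self.temporal:
            if "tau_gamma" not in self.fixed:
                st.tau_gamma = rng.gamma(a + s.T / 2.0,
                                         1.0 / (b + 0.5 * float(st.gamma @ st.gamma)))
            if "tau_phi" not in self.fixed:
                dphi = np.diff(st.phi)
                st.tau_phi = rng.gamma(a + (s.T - 1) / 2.0,
                                       1.0 / (b + 0.5 * float(dphi @ dphi)))

    # -- full run ----------------------------------------------------------

    def run(self) -> PosteriorDraws:
        opt = self.opt
        n, T, p = self.s.n, self.s.T, self.p
        m = opt.n_retained
        param_names = ["alpha"] + [f"beta:{j}" for j in range(p)] + ["tau_u", "tau_eta"]
        if self.temporal:
            param_names += ["tau_gamma", "tau_phi"]
        params = {name: np.empty((opt.n_chains, m)) for name in param_names}
        latent = {"u": np.empty((opt.n_chains, m, n)), "eta": np.empty((opt.n_chains, m, n))}
        if self.temporal:
            latent["gamma"] = np.empty((opt.n_chains, m, T))
            latent["phi"] = np.empty((opt.n_chains, m, T))
        accept_totals = {}

        seeds = np.random.SeedSequence(opt.seed).spawn(opt.n_chains)
        for c in range(opt.n_chains):
            rng = np.random.default_rng(seeds[c])
            st = self.init_state(rng)
            ls = self.init_scales()
            acc = self._zero_acc()
            post_acc = self._zero_acc()
            kept = 0
            for it in range(1, opt.n_iterations + 1):
                burnin = it <= opt.n_burnin
                self.sweep(st, rng, ls, acc if burnin else post_acc)
                if burnin and it % opt.adapt_every == 0:
                    self._adapt(ls, acc, opt.adapt_every)
                    acc = self._zero_acc()
                if not burnin and (it - opt.n_burnin) % opt.thin == 0 and kept < m:
                    params["alpha"][c, kept] = st.alpha - (
                        float(st.beta @ self.xmean) if p else 0.0)
                    for j in range(p):
                        params[f"beta:{j}"][c, kept] = st.beta[j]
                    params["tau_u"][c, kept] = st.tau_u
                    params["tau_eta"][c, kept] = st.tau_eta
                    latent["u"][c, kept] = st.u
                    latent["eta"][c, kept] = st.eta
                    if self.temporal:
                        params["tau_gamma"][c, kept] = st.tau_gamma
                        params["tau_phi"][c, kept] = st.tau_phi
                        latent["gamma"][c, kept] = st.gamma
                        latent["phi"][c, kept] = st.phi
                    kept += 1
            n_post = opt.n_iterations - opt.n_burnin
            for k, v in post_acc.items():
                accept_totals.setdefault(k, []).append(np.mean(v) / n_post)
        acceptance = {k: float(np.mean(v)) for k, v in accept_totals.items()}
        return PosteriorDraws(params, latent, acceptance, opt.seed, opt,
                              self.s.graph.region_ids, None, ())

    def _zero_acc(self):
        acc = {"u": np.zeros(self.s.n), "eta": np.zeros(self.s.n),
               "alpha": 0.0, "swap_u": 0.0}
        if self.p:
            acc["beta"] = np.zeros(self.p)
        if self.temporal:
            acc["gamma"] = np.zeros(self.s.T)
            acc["phi"] = np.zeros(self.s.T)
            acc["swap_gamma"] = 0.0
        return acc

    def _adapt(self, ls, acc, window, step: float = 0.4):
        target = self.opt.target_accept
        for key in ls:
            ls[key] = ls[key] + step * (acc[key] / window - target)


# ---------------------------------------------------------------------------
# public model classes (statsmodels-style: Model -> fit() -> Results)


class SpatialCountModel:
    """BYM-type spatial Poisson model for region-level counts.

    Parameters
    ----------
    counts
        CountTable with observed Y and positive expected E per region
        (1-D; use :class:`SpatioTemporalCountModel` for period data).
    graph
        Binary contiguity RegionGraph; region order must match counts.
    covariates
        Optional CovariateTable (or (n, p) array) of region covariates.
    covariate_names
        Subset/order of covariate columns to include; defaults to all.
    """

    temporal = False

    def __init__(self, counts: CountTable, graph: RegionGraph,
                 covariates: CovariateTable | np.ndarray | None = None,
                 covariate_names: tuple | None = None,
                 priors: PriorSpec | None = None):
        if tuple(counts.region_ids) != tuple(graph.region_ids):
            raise ModelInputError("counts and graph must cover the same regions "
                                  "in the same order")
        Y = np.asarray(counts.Y, dtype=float)
        E = np.asarray(counts.E, dtype=float) if counts.E is not None else None
        if E is None:
            raise ModelInputError("counts.E is required (run expected_counts first)")
        self._check_shape(Y, E, counts)
        if np.any(self._total_E(E) <= 0):
            raise ModelInputError("all regions must have positive expected counts; "
                                  "drop zero-E regions first (cohort.drop_zero_expected)")
        self.counts = counts
        self.graph = graph
        self.priors = priors or PriorSpec()
        self.Y2 = Y if Y.ndim == 2 else Y[:, None]
        self.E2 = E if E.ndim == 2 else E[:, None]
        if covariates is None:
            self.X = None
            self.covariate_names = ()
        elif isinstance(covariates, CovariateTable):
            if tuple(covariates.region_ids) != tuple(graph.region_ids):
                raise ModelInputError("covariates not aligned to graph regions")
            names = tuple(covariate_names) if covariate_names else covariates.names
            unknown = set(names) - set(covariates.names)
            if unknown:
                raise ModelInputError(f"unknown covariate names: {sorted(unknown)}")
            self.X = np.column_stack([getattr(covariates, nm) for nm in names])
            self.covariate_names = names
        else:
            self.X = np.atleast_2d(np.asarray(covariates, dtype=float))
            if self.X.shape[0] != graph.n_regions:
                self.X = self.X.T
            self.covariate_names = tuple(covariate_names) if covariate_names else tuple(
                f"x{j}" for j in range(self.X.shape[1]))

    @staticmethod
    def _check_shape(Y, E, counts):
        if Y.ndim != 1:
            raise ModelInputError("spatial model expects 1-D counts; "
                                  "use SpatioTemporalCountModel for period tables")
        if Y.shape != E.shape:
            raise ModelInputError("Y and E shapes differ")

    @staticmethod
    def _total_E(E):
        return E if E.ndim == 1 else E.sum(axis=1)

    @classmethod
    def from_tables(cls, cases, populations, graph, covariates=None, **kwargs):
        """Convenience constructor from line-list cases and stratum populations."""
        from .cohort import expected_counts
        table = expected_counts(cases, populations, graph.region_ids,
                                sex=kwargs.pop("sex", None),
                                subsite=kwargs.pop("subsite", None))
        return cls(table, graph, covariates=covariates, **kwargs)

    def _structure(self) -> _Structure:
        return _Structure(self.graph, 1)

    def fit(self, n_chains: int = 4, n_iterations: int = 30_000, n_burnin: int = 10_000,
            thin: int = 10, seed: int = 0, fixed_precisions: dict | None = None,
            options: SamplerOptions | None = None):
        """Run the Metropolis-within-Gibbs sampler and return results.

        Any explicit ``options`` object overrides the keyword budget.
        """
        from .results import CountModelResults
        opt = options or SamplerOptions(n_chains=n_chains, n_iterations=n_iterations,
                                        n_burnin=n_burnin, thin=thin, seed=seed,
                                        fixed_precisions=fixed_precisions)
        sampler = _GibbsSampler(self.Y2, self.E2, self.X, self._structure(),
                                self.priors, opt)
        draws = sampler.run()
        draws = self._relabel(draws)
        return CountModelResults(self, draws)

    def _relabel(self, draws: PosteriorDraws) -> PosteriorDraws:
        params = {}
        for name, arr in draws.params.items():
            if name.startswith("beta:"):
                j = int(name.split(":")[1])
                params[f"beta:{self.covariate_names[j]}"] = arr
            else:
                params[name] = arr
        periods = self.counts.periods if self.temporal else None
        return PosteriorDraws(params, draws.latent, draws.acceptance, draws.seed,
                              draws.options, self.graph.region_ids, periods,
                              self.covariate_names)

    def sample_prior(self, n_draws: int = 10_000, seed: int = 0) -> PosteriorDraws:
        """Exact draws from the joint prior (the posterior with no data).

        With the likelihood removed the model is just its prior, which is
        sampled ancestrally: precisions from Gamma(shape, rate), then
        effects given precisions — u and gamma iid Gaussian, eta and phi
        exact constrained ICAR / RW(1) fields.  The flat-prior intercept
        has no proper distribution and is reported as 0.
        """
        from .simulate import simulate_structured_field
        rng = np.random.default_rng(seed)
        pr = self.priors
        n, p = self.graph.n_regions, len(self.covariate_names) or (self.X.shape[1] if self.X is not None else 0)
        a, b = pr.precision_shape, pr.precision_rate
        tau_u = rng.gamma(a, 1.0 / b, size=n_draws)
        tau_eta = rng.gamma(a, 1.0 / b, size=n_draws)
        u = rng.normal(size=(n_draws, n)) / np.sqrt(tau_u)[:, None]
        eta = simulate_structured_field(self.graph, 1.0, rng, size=n_draws)
        eta = eta / np.sqrt(tau_eta)[:, None]
        params = {"alpha": np.zeros((1, n_draws)),
                  "tau_u": tau_u[None, :], "tau_eta": tau_eta[None, :]}
        for j, nm in enumerate(self.covariate_names):
            params[f"beta:{nm}"] = (pr.beta_mean + np.sqrt(pr.beta_var)
                                    * rng.normal(size=(1, n_draws)))
        latent = {"u": u[None], "eta": eta[None]}
        if self.temporal:
            T = self.Y2.shape[1]
            tau_gamma = rng.gamma(a, 1.0 / b, size=n_draws)
            tau_phi = rng.gamma(a, 1.0 / b, size=n_draws)
            gamma = rng.normal(size=(n_draws, T)) / np.sqrt(tau_gamma)[:, None]
            phi = simulate_structured_field(make_lattice(1, T), 1.0, rng, size=n_draws)
            phi = phi / np.sqrt(tau_phi)[:, None]
            params["tau_gamma"] = tau_gamma[None, :]
            params["tau_phi"] = tau_phi[None, :]
            latent["gamma"] = gamma[None]
            latent["phi"] = phi[None]
        opt = SamplerOptions(n_chains=1, n_iterations=n_draws, n_burnin=0, thin=1, seed=seed)
        return PosteriorDraws(params, latent, {}, seed, opt, self.graph.region_ids,
                              self.counts.periods if self.temporal else None,
                              self.covariate_names)


class SpatioTemporalCountModel(SpatialCountModel):
    """Additive space-time BYM model with exchangeable + RW(1) period effects."""

    temporal = True

    @staticmethod
    def _check_shape(Y, E, counts):
        if Y.ndim != 2 or Y.shape[1] < 2:
            raise ModelInputError("spatio-temporal model needs a (regions x periods) "
                                  "table with T >= 2; use SpatialCountModel for T = 1")
        if Y.shape != E.shape:
            raise ModelInputError("Y and E shapes differ")
        if np.any(np.asarray(E) < 0):
            raise ModelInputError("negative expected counts")

    def _structure(self) -> _Structure:
        return _Structure(self.graph, self.Y2.shape[1])

    @classmethod
    def from_tables(cls, cases, populations, graph, covariates=None, **kwargs):
        # pooled reference rates: temporal trends stay in the data so the
        # gamma/phi effects can estimate them
        from .cohort import DEFAULT_PERIODS, expected_counts_by_period
        table = expected_counts_by_period(
            cases, populations, graph.region_ids,
            period_scheme=kwargs.pop("period_scheme", DEFAULT_PERIODS),
            sex=kwargs.pop("sex", None), subsite=kwargs.pop("subsite", None),
            rates=kwargs.pop("rates", "pooled"))
        return cls(table, graph, covariates=covariates, **kwargs)


def fit_spatial(counts, covariates, graph, priors=None, **fit_kwargs):
    """Functional wrapper: build a SpatialCountModel and fit it."""
    return SpatialCountModel(counts, graph, covariates=covariates, priors=priors).fit(**fit_kwargs)


def fit_spatiotemporal(counts, covariates, graph, priors=None, **fit_kwargs):
    """Functional wrapper: build a SpatioTemporalCountModel and fit it."""
    return SpatioTemporalCountModel(counts, graph, covariates=covariates, priors=priors).fit(**fit_kwargs)
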