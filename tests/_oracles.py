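"""Independent oracles used by the test suite.

Deliberately naive implementations (brute-force double loops, BFS,
deterministic quadrature) that share no code with the package internals.
"""

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import gammaln


def morans_i_bruteforce(values, graph):
    """O(n^2) double-loop evaluation of Moran's I with binary weights."""
    y = np.asarray(values, dtype=float)
    n = len(y)
    nbrs = graph.neighbor_sets()
    ybar = y.mean()
    num = 0.0
    s0 = 0
    for i in range(n):
        for j in range(n):
            w = 1.0 if j in nbrs[i] else 0.0
            num += w * (y[i] - ybar) * (y[j] - ybar)
            s0 += w
    den = np.sum((y - ybar) ** 2)
    return (n / s0) * num / den


def bfs_components(graph):
    """Breadth-first-search component labels (first-seen order)."""
    nbrs = graph.neighbor_sets()
    n = graph.n_regions
    labels = [-1] * n
    c = 0
    for start in range(n):
        if labels[start] >= 0:
            continue
        queue = [start]
        labels[start] = c
        while queue:
            v = queue.pop(0)
            for w in nbrs[v]:
                if labels[w] < 0:
                    labels[w] = c
                    queue.append(w)
        c += 1
    return np.array(labels)


def pairwise_quadratic_bruteforce(eta, graph):
    """sum over unordered neighbor pairs of (eta_i - eta_j)^2 by double loop."""
    nbrs = graph.neighbor_sets()
    total = 0.0
    for i in range(graph.n_regions):
        for j in nbrs[i]:
            if j > i:
                total += (eta[i] - eta[j]) ** 2
    return total


def spatial_alpha_posterior_mean(Y, E, n_hermite=31, alpha_grid=None, z_grid=None):
    """Deterministic quadrature for the 3-region path-graph BYM posterior.

    Model: Y_i ~ Poisson(E_i exp(alpha + u_i + eta_i)), u_i ~ N(0,1),
    eta an ICAR field with unit variance constrained to sum to zero,
    flat prior on alpha.  u is integrated by Gauss-Hermite; (alpha, eta)
    on a product grid, eta parametrised in an orthonormal basis of the
    sum-to-zero subspace.  Returns the posterior mean of alpha.
    """
    Y = np.asarray(Y, dtype=float)
    E = np.asarray(E, dtype=float)
    b1 = np.array([1.0, 0.0, -1.0]) / np.sqrt(2)
    b2 = np.array([1.0, -2.0, 1.0]) / np.sqrt(6)
    alpha = np.arange(-2.5, 2.5001, 0.025) if alpha_grid is None else alpha_grid
    z = np.arange(-4.0, 4.0001, 0.08) if z_grid is None else z_grid
    A = alpha[:, None, None]
    Z1 = z[None, :, None]
    Z2 = z[None, None, :]
    x, w = hermgauss(n_hermite)
    u_nodes = np.sqrt(2.0) * x
    w = w / np.sqrt(np.pi)
    logpost = 0.0
    etas = []
    for i in range(3):
        eta_i = Z1 * b1[i] + Z2 * b2[i]
        etas.append(eta_i)
        S = A + eta_i
        g = np.zeros(np.broadcast(A, eta_i).shape)
        for uk, wk in zip(u_nodes, w):
            lam = E[i] * np.exp(S + uk)
            g += wk * np.exp(Y[i] * np.log(lam) - lam - gammaln(Y[i] + 1))
        logpost = logpost + np.log(g)
    q = (etas[0] - etas[1]) ** 2 + (etas[1] - etas[2]) ** 2
    logpost = logpost - 0.5 * q
    wgt = np.exp(logpost - logpost.max())
    return float((wgt * A).sum() / wgt.sum())


def spacetime_alpha_posterior_mean(Y, E, sigma2_u=1.0, sigma2_phi=1.0, n_hermite=21):
    """Quadrature for a 2-region x 2-period model with gamma suppressed.

    Model: Y_it ~ Poisson(E_it exp(alpha + u_i + eta_i + phi_t)) with
    u_i ~ N(0, sigma2_u), eta = (e, -e) an ICAR pair with unit variance,
    phi = (f, -f) an RW(1) pair with variance sigma2_phi, flat alpha.
    The exchangeable gamma effect is pinned at 0 (its precision fixed
    very large in the matching sampler run).
    """
    Y = np.asarray(Y, dtype=float)   # (2, 2)
    E = np.asarray(E, dtype=float)
    alpha = np.arange(-2.0, 2.0001, 0.02)
    ze = np.arange(-3.0, 3.0001, 0.05)   # eta basis coordinate
    zf = np.arange(-3.0, 3.0001, 0.05)   # phi basis coordinate
    A = alpha[:, None, None]
    ZE = ze[None, :, None]
    ZF = zf[None, None, :]
    be = np.array([1.0, -1.0]) / np.sqrt(2)
    bf = np.array([1.0, -1.0]) / np.sqrt(2)
    x, w = hermgauss(n_hermite)
    u_nodes = np.sqrt(2.0 * sigma2_u) * x
    w = w / np.sqrt(np.pi)
    logpost = 0.0
    for i in range(2):
        eta_i = ZE * be[i]
        # per-region integral over u_i of the two-period Poisson product
        g = np.zeros(np.broadcast(A, eta_i, ZF).shape)
        for uk, wk in zip(u_nodes, w):
            term = 0.0
            for t in range(2):
                lam = E[i, t] * np.exp(A + eta_i + uk + ZF * bf[t])
                term = term + Y[i, t] * np.log(lam) - lam - gammaln(Y[i, t] + 1)
            g += wk * np.exp(term)
        logpost = logpost + np.log(g)
    # ICAR pair prior: exp(-(eta_1-eta_2)^2/2) with unit variance
    logpost = logpost - 0.5 * (np.sqrt(2.0) * ZE) ** 2 + 0.0 * A
    # RW(1) pair prior with variance sigma2_phi
    logpost = logpost - 0.5 * (np.sqrt(2.0) * ZF) ** 2 / sigma2_phi
    wgt = np.exp(logpost - logpost.max())
    return float((wgt * A).sum() / wgt.sum())


def poisson_glm_loglik(beta, Y, E, D):
    eta = np.log(E) + D @ beta
    mu = np.exp(eta)
    return np.sum(Y * eta - mu)
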