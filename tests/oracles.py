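"""Independent reference implementations used only by the tests.

Everything here is written with explicit loops / exhaustive enumeration
and stays independent of the package's vectorised code paths.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import betaln, digamma, gammaln, logsumexp


def log_binom_coef(d, a):
    return gammaln(d + 1) - gammaln(a + 1) - gammaln(d - a + 1)


def naive_elbo(A, D, r, g, pi, U, alpha, beta, alpha0, beta0):
    """Term-by-term ELBO with explicit loops over i, j, k, t."""
    N, M = A.shape
    K = r.shape[1]
    T = len(alpha)
    el_t = digamma(alpha) - digamma(alpha + beta)
    el_1mt = digamma(beta) - digamma(alpha + beta)

    e_data = 0.0
    for i in range(N):
        for j in range(M):
            d, a = D[i, j], A[i, j]
            if d == 0:
                continue
            b = d - a
            e_data += log_binom_coef(d, a)
            for k in range(K):
                for t in range(T):
                    e_data += r[j, k] * g[i, k, t] * (a * el_t[t] + b * el_1mt[t])

    e_z = 0.0
    for j in range(M):
        for k in range(K):
            if r[j, k] > 0:
                e_z += r[j, k] * (np.log(pi[k]) - np.log(r[j, k]))

    e_g = 0.0
    for i in range(N):
        for k in range(K):
            for t in range(T):
                if g[i, k, t] > 0:
                    e_g += g[i, k, t] * (np.log(U[i, k, t]) - np.log(g[i, k, t]))

    e_theta = 0.0
    for t in range(T):
        kl = (
            betaln(alpha0[t], beta0[t])
            - betaln(alpha[t], beta[t])
            + (alpha[t] - alpha0[t]) * digamma(alpha[t])
            + (beta[t] - beta0[t]) * digamma(beta[t])
            + (alpha0[t] - alpha[t] + beta0[t] - beta[t])
            * digamma(alpha[t] + beta[t])
        )
        e_theta -= kl
    return e_data + e_z + e_g + e_theta


def naive_assignment_update(A, D, g, el_t, el_1mt, pi):
    """Scalar softmax re-implementation of the q(Z) update."""
    N, M = A.shape
    K = g.shape[1]
    T = g.shape[2]
    r = np.zeros((M, K))
    for j in range(M):
        logw = np.log(pi).copy()
        for k in range(K):
            for i in range(N):
                d, a = D[i, j], A[i, j]
                if d == 0:
                    continue
                b = d - a
                for t in range(T):
                    logw[k] += g[i, k, t] * (a * el_t[t] + b * el_1mt[t])
        logw -= logw.max()
        w = np.exp(logw)
        r[j] = w / w.sum()
    return r


def naive_genotype_update(A, D, r, el_t, el_1mt, U):
    """Scalar softmax re-implementation of the q(G) update."""
    N, M = A.shape
    K = r.shape[1]
    T = U.shape[2]
    g = np.zeros((N, K, T))
    for i in range(N):
        for k in range(K):
            logw = np.log(U[i, k]).copy()
            for t in range(T):
                for j in range(M):
                    d, a = D[i, j], A[i, j]
                    if d == 0:
                        continue
                    b = d - a
                    logw[t] += r[j, k] * (a * el_t[t] + b * el_1mt[t])
            logw -= logw.max()
            w = np.exp(logw)
            g[i, k] = w / w.sum()
    return g


def enumerate_posterior(A, D, U, pi, alpha0, beta0):
    """Exact enumeration over all Z and G configurations.

    theta is integrated out analytically per configuration (beta-binomial
    conjugacy).  Returns (log_marginal, p_z) where p_z[j, k] is the exact
    marginal posterior that cell j belongs to donor k.
    """
    N, M = A.shape
    K = pi.shape[0]
    T = 3
    logc = 0.0
    for i in range(N):
        for j in range(M):
            if D[i, j] > 0:
                logc += log_binom_coef(D[i, j], A[i, j])

    g_configs = list(itertools.product(range(T), repeat=N * K))
    z_configs = list(itertools.product(range(K), repeat=M))
    logps = np.empty((len(z_configs), len(g_configs)))
    for zi, z in enumerate(z_configs):
        for gi, gcfg in enumerate(g_configs):
            G = np.array(gcfg).reshape(N, K)
            lp = logc
            for j in range(M):
                lp += np.log(pi[z[j]])
            for i in range(N):
                for k in range(K):
                    lp += np.log(U[i, k, G[i, k]])
            # sufficient statistics per theta state
            at = np.zeros(T)
            bt = np.zeros(T)
            for i in range(N):
                for j in range(M):
                    if D[i, j] == 0:
                        continue
                    t = G[i, z[j]]
                    at[t] += A[i, j]
                    bt[t] += D[i, j] - A[i, j]
            for t in range(T):
                lp += betaln(alpha0[t] + at[t], beta0[t] + bt[t]) - betaln(
                    alpha0[t], beta0[t]
                )
            logps[zi, gi] = lp

    log_marginal = logsumexp(logps)
    per_z = logsumexp(logps, axis=1)
    p_z = np.zeros((M, K))
    for zi, z in enumerate(z_configs):
        w = np.exp(per_z[zi] - log_marginal)
        for j in range(M):
            p_z[j, z[j]] += w
    return log_marginal, p_z


def random_instance(rng, N=3, M=3, K=2, informative_prior=True, depth=3.0):
    """A tiny random dataset plus a (possibly symmetry-breaking) prior."""
    U = (
        rng.dirichlet(np.ones(3), size=(N, K))
        if informative_prior
        else np.full((N, K, 3), 1.0 / 3.0)
    )
    pi = np.full(K, 1.0 / K)
    theta_true = np.array([0.01, 0.5, 0.99])
    G = np.array([[rng.choice(3, p=U[i, k]) for k in range(K)] for i in range(N)])
    z = rng.integers(0, K, size=M)
    D = rng.poisson(depth, size=(N, M))
    A = rng.binomial(D, theta_true[G[np.arange(N)[:, None], z[None, :]]])
    return A, D, U, pi, G, z
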