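"""Compiled numerical core of the stage-specific growth model.

The parameter vector layout (transformed scale used by the sampler) is

    [L_inf, log K, t0, log tau, theta (concatenated stages 1..3),
     mu_init (site-major, ages 2..6)]

``tau`` is the Normal observation precision (sigma = tau**-0.5).  The
sampler is the same adaptive block random-walk Metropolis as
:func:`graylinggrowth.mcmc.run_mcmc`, compiled so that the many refits of
the simplification procedure stay cheap.
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_AGES = 6
LOG2PI = float(np.log(2.0 * np.pi))


@njit(cache=True)
def compute_mu(Linf, K, t0, theta, mu_init, X, M, literal):
    """Expected length mu[y, s, a] under the stage-covariate recursion.

    theta is the concatenated coefficient vector (stage 1 first);
    X has shape (Y, S, 3, Mmax); M[l] is the stage-l coefficient count;
    mu_init[s, a-2] holds the first-year expected lengths for ages 2..6.
    With ``literal`` the increment is not added to the previous length
    (the printed-equation variant).
    """
    Y, S = X.shape[0], X.shape[1]
    mu = np.empty((Y, S, N_AGES))
    G = np.empty(N_AGES + 1)
    for a in range(1, N_AGES + 1):
        G[a] = 1.0 - np.exp(-K * (a - t0))
    off1 = M[0]
    off2 = M[0] + M[1]
    for y in range(Y):
        for s in range(S):
            e = 0.0
            for m in range(M[0]):
                e += theta[m] * X[y, s, 0, m]
            mu[y, s, 0] = Linf * G[1] * np.exp(e)
    for s in range(S):
        for a in range(2, N_AGES + 1):
            mu[0, s, a - 1] = mu_init[s, a - 2]
    for y in range(1, Y):
        for s in range(S):
            for a in range(2, N_AGES + 1):
                l = 1 if a == 2 else 2  # 0-based stage index
                off = off1 if l == 1 else off2
                e = 0.0
                for m in range(M[l]):
                    e += theta[off + m] * X[y, s, l, m]
                prev = mu[y - 1, s, a - 2]
                inc = (Linf - prev) * G[a] * np.exp(e)
                mu[y, s, a - 1] = inc if literal else prev + inc
    return mu


@njit(cache=True)
def log_post(x, X, M, n, s1, s2, prior, literal):
    """Unnormalised log posterior from per-cell sufficient statistics.

    ``n``, ``s1``, ``s2`` hold per (year, site, age) the record count, sum
    of lengths and sum of squared lengths.  ``prior`` packs
    [linf_prec, t0_prec, k_shape, k_rate, eps_shape, eps_rate,
     beta_prec, mu_init_prec].
    """
    Linf = x[0]
    K = np.exp(x[1])
    t0 = x[2]
    log_tau = x[3]
    tau = np.exp(log_tau)
    npar = x.shape[0]
    n_theta = M[0] + M[1] + M[2]
    S = X.shape[1]

    lp = -0.5 * prior[0] * Linf * Linf
    lp += -0.5 * prior[1] * t0 * t0
    lp += prior[2] * x[1] - prior[3] * K  # Gamma prior on K + log-Jacobian
    lp += prior[4] * log_tau - prior[5] * tau  # Gamma prior on tau + Jacobian
    for j in range(4, 4 + n_theta):
        lp += -0.5 * prior[6] * x[j] * x[j]
    for j in range(4 + n_theta, npar):
        lp += -0.5 * prior[7] * x[j] * x[j]

    theta = x[4 : 4 + n_theta]
    mu_init = x[4 + n_theta :].reshape(S, N_AGES - 1).copy()
    mu = compute_mu(Linf, K, t0, theta, mu_init, X, M, literal)
    Y = X.shape[0]
    for y in range(Y):
        for s in range(S):
            for a in range(N_AGES):
                nc = n[y, s, a]
                if nc > 0:
                    m = mu[y, s, a]
                    lp += -0.5 * nc * (LOG2PI - log_tau)
                    lp += -0.5 * tau * (s2[y, s, a] - 2.0 * m * s1[y, s, a] + nc * m * m)
    return lp


@njit(cache=True)
def _gibbs_linf(x, X, M, n, s1, s2, prior, literal):
    """Exact Normal draw of L_inf | everything else.

    Every cell's expected length is affine in L_inf (the juvenile equation
    is proportional to it; each increment recursion step is affine), so
    with the Gaussian likelihood and Normal prior the conditional is
    conjugate.  The affine coefficients come from two recursion passes at
    L_inf = 0 and L_inf = 1.
    """
    n_theta = M[0] + M[1] + M[2]
    S = X.shape[1]
    Y = X.shape[0]
    K = np.exp(x[1])
    t0 = x[2]
    tau = np.exp(x[3])
    theta = x[4 : 4 + n_theta]
    mu_init = x[4 + n_theta :].reshape(S, N_AGES - 1).copy()
    A = compute_mu(0.0, K, t0, theta, mu_init, X, M, literal)
    B = compute_mu(1.0, K, t0, theta, mu_init, X, M, literal) - A
    prec = prior[0]
    mean_num = 0.0
    for y in range(Y):
        for s in range(S):
            for a in range(N_AGES):
                nc = n[y, s, a]
                if nc > 0:
                    b = B[y, s, a]
                    prec += tau * nc * b * b
                    mean_num += tau * b * (s1[y, s, a] - nc * A[y, s, a])
    x[0] = mean_num / prec + np.random.standard_normal() / np.sqrt(prec)


@njit(cache=True)
def _gibbs_tau(x, X, M, n, s1, s2, prior, literal):
    """Exact draw of the observation precision tau | mu (conjugate Gamma)."""
    n_theta = M[0] + M[1] + M[2]
    S = X.shape[1]
    theta = x[4 : 4 + n_theta]
    mu_init = x[4 + n_theta :].reshape(S, N_AGES - 1).copy()
    mu = compute_mu(x[0], np.exp(x[1]), x[2], theta, mu_init, X, M, literal)
    sse = 0.0
    ntot = 0.0
    Y = X.shape[0]
    for y in range(Y):
        for s in range(S):
            for a in range(N_AGES):
                nc = n[y, s, a]
                if nc > 0:
                    m = mu[y, s, a]
                    sse += s2[y, s, a] - 2.0 * m * s1[y, s, a] + nc * m * m
                    ntot += nc
    shape = prior[4] + 0.5 * ntot
    rate = prior[5] + 0.5 * max(sse, 0.0)
    tau = np.random.gamma(shape, 1.0 / rate)
    x[3] = np.log(tau)


@njit(cache=True)
def _gibbs_mu_init(x, X, M, n, s1, s2, prior, literal):
    """Exact Normal draws of each first-year expected length | the rest.

    Along a cohort the recursion is affine in its starting value
    (mu_next = mult * mu + add with mult = 1 - G*E, or -G*E in literal
    form), so the Gaussian likelihood of all downstream cells combines with
    the Normal prior conjugately.
    """
    n_theta = M[0] + M[1] + M[2]
    S = X.shape[1]
    Y = X.shape[0]
    Linf = x[0]
    K = np.exp(x[1])
    t0 = x[2]
    tau = np.exp(x[3])
    theta = x[4 : 4 + n_theta]
    off1 = M[0]
    off2 = M[0] + M[1]
    G = np.empty(N_AGES + 1)
    for a in range(1, N_AGES + 1):
        G[a] = 1.0 - np.exp(-K * (a - t0))
    for s in range(S):
        for a0 in range(2, N_AGES + 1):
            prec = prior[7]
            mean_num = 0.0
            d = 1.0
            c = 0.0
            y = 0
            a = a0
            while True:
                nc = n[y, s, a - 1]
                if nc > 0:
                    prec += tau * nc * d * d
                    mean_num += tau * d * (s1[y, s, a - 1] - nc * c)
                if a == N_AGES or y == Y - 1:
                    break
                a += 1
                y += 1
                l = 1 if a == 2 else 2
                off = off1 if l == 1 else off2
                e = 0.0
                for m in range(M[l]):
                    e += theta[off + m] * X[y, s, l, m]
                ge = G[a] * np.exp(e)
                if literal:
                    d = -d * ge
                    c = (Linf - c) * ge
                else:
                    d = d * (1.0 - ge)
                    c = c * (1.0 - ge) + Linf * ge
            mean = mean_num / prec
            x[4 + n_theta + s * (N_AGES - 1) + (a0 - 2)] = (
                mean + np.random.standard_normal() / np.sqrt(prec)
            )


@njit(cache=True)
def sample_chain(
    x0,
    iterations,
    burn_in,
    thin,
    seed,
    block_start,
    block_len,
    X,
    M,
    n,
    s1,
    s2,
    prior,
    literal,
):
    """One Metropolis-within-Gibbs chain (compiled).

    The core (L_inf, log K, t0) and each stage's theta vector are adaptive
    block random-walk Metropolis updates (scaled empirical covariance,
    Robbins--Monro global step targeting 23.4% acceptance, adaptation
    frozen after burn-in).  The observation precision and the first-year
    expected lengths are exact conjugate Gibbs draws.  Reproducible given
    ``seed``.
    """
    np.random.seed(seed)
    npar = x0.shape[0]
    nb = block_start.shape[0]
    dmax = int(block_len.max())
    x = x0.copy()
    lp = log_post(x, X, M, n, s1, s2, prior, literal)

    log_scale = np.zeros(nb)
    means = np.zeros((nb, dmax))
    covs = np.zeros((nb, dmax, dmax))
    chols = np.zeros((nb, dmax, dmax))
    counts = np.zeros(nb)
    for bi in range(nb):
        d = block_len[bi]
        for j in range(d):
            means[bi, j] = x[block_start[bi] + j]
            covs[bi, j, j] = 0.01
            chols[bi, j, j] = 0.1

    retained = (iterations - burn_in) // thin
    kept = np.empty((retained, npar))
    ki = 0
    prop = np.empty(npar)
    delta = np.empty(dmax)
    for it in range(iterations):
        adapting = it < burn_in
        for bi in range(nb):
          # the (log K, t0) block mixes slowest; give it extra sub-updates
          for _rep in range(4 if bi == 0 else 1):
            st = block_start[bi]
            d = block_len[bi]
            step = np.exp(log_scale[bi]) * 2.38 / np.sqrt(d)
            for j in range(npar):
                prop[j] = x[j]
            z = np.random.standard_normal(d)
            for j in range(d):
                dx = 0.0
                for jj in range(j + 1):
                    dx += chols[bi, j, jj] * z[jj]
                prop[st + j] = x[st + j] + step * dx
            lp_prop = log_post(prop, X, M, n, s1, s2, prior, literal)
            acc = np.log(np.random.random()) < lp_prop - lp
            if acc:
                for j in range(d):
                    x[st + j] = prop[st + j]
                lp = lp_prop
            if adapting:
                gamma = min(0.25, 5.0 / np.sqrt(it + 10.0))
                log_scale[bi] += gamma * ((1.0 if acc else 0.0) - 0.234)
                counts[bi] += 1.0
                w = 1.0 / (counts[bi] + 5.0)
                for j in range(d):
                    delta[j] = x[st + j] - means[bi, j]
                    means[bi, j] += w * delta[j]
                for j in range(d):
                    for jj in range(d):
                        covs[bi, j, jj] = (1.0 - w) * covs[bi, j, jj] + w * delta[
                            j
                        ] * delta[jj]
                if counts[bi] % 50 == 0:
                    A = np.empty((d, d))
                    for j in range(d):
                        for jj in range(d):
                            A[j, jj] = covs[bi, j, jj]
                        A[j, j] += 1e-9
                    L = np.linalg.cholesky(A)
                    for j in range(d):
                        for jj in range(d):
                            chols[bi, j, jj] = L[j, jj]
        _gibbs_linf(x, X, M, n, s1, s2, prior, literal)
        _gibbs_tau(x, X, M, n, s1, s2, prior, literal)
        _gibbs_mu_init(x, X, M, n, s1, s2, prior, literal)
        lp = log_post(x, X, M, n, s1, s2, prior, literal)
        if it >= burn_in and (it - burn_in) % thin == 0 and ki < retained:
            for j in range(npar):
                kept[ki, j] = x[j]
            ki += 1
    return kept
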