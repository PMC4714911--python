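"""Numba kernels for the Metropolis-within-Gibbs sampler.

The chain spends essentially all of its time evaluating the projected Wishart
log likelihood, so the whole update loop lives here as nopython code. State
is held in flat arrays:

* ``alpha`` -- (3,) decay-curve parameters
* ``eta``, ``w`` -- (K,) nuggets and admixture proportions
* ``X`` -- (2K, 2) locations; rows 0..K-1 are population locations G, rows
  K..2K-1 the admixture sources G*. Spherical coordinates are (lon, lat) in
  radians; planar coordinates are raw (x, y).
* ``D``, ``F`` -- (2K, 2K) pairwise distances and the powered-exponential
  decay ``exp(-(alpha1 D)**alpha2)`` (the 1/alpha0 factor is applied inside
  the likelihood), maintained incrementally: a location move touches one
  row/column, an alpha1/alpha2 move triggers a full refill, and alpha0,
  eta and w moves leave them untouched.

Update blocks are indexed 0..3+4K-1: [alpha0, alpha1, alpha2, eta_1..K,
w_1..K, G_1..K, G*_1..K]; a model variant is expressed by the list of free
block indices handed to :func:`run_chain`.
"""

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi


@njit(cache=True)
def pair_distance(x1, y1, x2, y2, metric):
    """Distance between two points; metric 0 = planar, 1 = unit sphere."""
    if metric == 0:
        dx = x1 - x2
        dy = y1 - y2
        return np.sqrt(dx * dx + dy * dy)
    # haversine on (lon, lat) in radians
    h = (
        np.sin((y2 - y1) / 2.0) ** 2
        + np.cos(y1) * np.cos(y2) * np.sin((x2 - x1) / 2.0) ** 2
    )
    if h < 0.0:
        h = 0.0
    elif h > 1.0:
        h = 1.0
    return 2.0 * np.arcsin(np.sqrt(h))


@njit(cache=True)
def destination_point(lon, lat, bearing, arc):
    """Great-circle destination at ``arc`` radians along ``bearing``.

    Standard spherical destination formulas; longitude wrapped to (-pi, pi].
    """
    sin_lat2 = np.sin(lat) * np.cos(arc) + np.cos(lat) * np.sin(arc) * np.cos(
        bearing
    )
    if sin_lat2 > 1.0:
        sin_lat2 = 1.0
    elif sin_lat2 < -1.0:
        sin_lat2 = -1.0
    lat2 = np.arcsin(sin_lat2)
    lon2 = lon + np.arctan2(
        np.sin(bearing) * np.sin(arc) * np.cos(lat),
        np.cos(arc) - np.sin(lat) * sin_lat2,
    )
    lon2 = (lon2 + np.pi) % TWO_PI - np.pi
    if lon2 <= -np.pi:
        lon2 += TWO_PI
    return lon2, lat2


@njit(cache=True)
def decay_value(d, a1, a2):
    """exp(-(a1 d)^a2) via log/exp (cheaper than pow for repeated calls)."""
    if d <= 0.0:
        return 1.0
    t = a2 * (np.log(a1) + np.log(d))
    if t > 700.0:
        return 0.0
    return np.exp(-np.exp(t))


@njit(cache=True)
def fill_distances(X, metric, D):
    n = X.shape[0]
    for i in range(n):
        D[i, i] = 0.0
        for j in range(i + 1, n):
            d = pair_distance(X[i, 0], X[i, 1], X[j, 0], X[j, 1], metric)
            D[i, j] = d
            D[j, i] = d


@njit(cache=True)
def fill_decay(D, a1, a2, F):
    n = D.shape[0]
    for i in range(n):
        F[i, i] = 1.0
        for j in range(i + 1, n):
            v = decay_value(D[i, j], a1, a2)
            F[i, j] = v
            F[j, i] = v


@njit(cache=True)
def loglik_kernel(F, a0, eta, w, inv_sbar, psi, U, Ldf):
    """Model-dependent part of the projected Wishart log density.

    Returns ``-(L/2) logdet(Sigma) - (1/2) tr(Sigma^-1 A)`` where
    ``Sigma = psi' Omega* psi`` and ``A = U U'`` is the (precomputed
    Cholesky-factored) projected scaled sample covariance. ``-inf`` when
    Sigma is not positive definite.
    """
    K = eta.shape[0]
    p = K - 1
    inv_a0 = 1.0 / a0
    Om = np.empty((K, K))
    for i in range(K):
        for j in range(K):
            Om[i, j] = (
                (1.0 - w[i]) * (1.0 - w[j]) * F[i, j]
                + w[i] * (1.0 - w[j]) * F[K + i, j]
                + w[j] * (1.0 - w[i]) * F[i, K + j]
                + w[i] * w[j] * F[K + i, K + j]
            ) * inv_a0
        Om[i, i] += eta[i] + inv_sbar[i]
    W = Om @ psi
    M = psi.T @ W
    # in-place lower Cholesky; failure => not positive definite
    for j in range(p):
        s = M[j, j]
        for k in range(j):
            s -= M[j, k] * M[j, k]
        if s <= 0.0 or not np.isfinite(s):
            return -np.inf
        M[j, j] = np.sqrt(s)
        inv = 1.0 / M[j, j]
        for i in range(j + 1, p):
            t = M[i, j]
            for k in range(j):
                t -= M[i, k] * M[j, k]
            M[i, j] = t * inv
    logdet = 0.0
    for j in range(p):
        logdet += 2.0 * np.log(M[j, j])
    # tr(Sigma^-1 A) = ||C^-1 U||_F^2 with Sigma = C C'
    tr = 0.0
    y = np.empty(p)
    for c in range(p):
        for i in range(p):
            t = U[i, c]
            for k in range(i):
                t -= M[i, k] * y[k]
            y[i] = t / M[i, i]
            tr += y[i] * y[i]
    return -0.5 * Ldf * logdet - 0.5 * tr


# ---------------------------------------------------------------------------
# log prior terms (shared, via thin wrappers, with the Python-level API)
# ---------------------------------------------------------------------------


@njit(cache=True)
def logp_exponential(x, rate):
    if x < 0.0:
        return -np.inf
    return np.log(rate) - rate * x

@njit(cache=True)
def logp_uniform(x, lo, hi):
    if x <= lo or x > hi:
        return -np.inf
    return -np.log(hi - lo)


@njit(cache=True)
def logp_admixture(wk, beta_b):
    """Density of w when 2w ~ Beta(1, beta_b), change of variables included."""
    if wk < 0.0 or wk >= 0.5:
        return -np.inf
    return np.log(2.0 * beta_b) + (beta_b - 1.0) * np.log1p(-2.0 * wk)


@njit(cache=True)
def logp_location(x, y, mux, muy, sigma, metric):
    """Isotropic Gaussian in distance from the prior center (unnormalized)."""
    d = pair_distance(x, y, mux, muy, metric)
    return -0.5 * d * d / (sigma * sigma)


@njit(cache=True)
def total_log_prior(
    alpha, eta, w, X, metric,
    a0_rate, a1_rate, a2_lo, a2_hi, eta_rate, w_beta_b,
    mu_G, sigma_G, mu_Gs, sigma_Gs,
    free_eta, free_w, free_G, free_Gs,
):
    K = eta.shape[0]
    lp = (
        logp_exponential(alpha[0], a0_rate)
        + logp_exponential(alpha[1], a1_rate)
        + logp_uniform(alpha[2], a2_lo, a2_hi)
    )
    if free_eta:
        for k in range(K):
            lp += logp_exponential(eta[k], eta_rate)
    if free_w:
        for k in range(K):
            lp += logp_admixture(w[k], w_beta_b)
    if free_G:
        for k in range(K):
            lp += logp_location(
                X[k, 0], X[k, 1], mu_G[k, 0], mu_G[k, 1], sigma_G, metric
            )
    if free_Gs:
        for k in range(K):
            lp += logp_location(
                X[K + k, 0], X[K + k, 1], mu_Gs[0], mu_Gs[1], sigma_Gs, metric
            )
    return lp


@njit(cache=True)
def adapt_amount(n):
    a = n ** (-0.5)
    if a > 0.01:
        a = 0.01
    return a


@njit(cache=True)
def run_chain(
    seed,
    n_iter,
    thin,
    adapt_every,
    adapt_on,
    metric,
    psi,
    U,
    Ldf,
    inv_sbar,
    free_blocks,
    a0_rate,
    a1_rate,
    a2_lo,
    a2_hi,
    eta_rate,
    w_beta_b,
    mu_G,
    sigma_G,
    mu_Gs,
    sigma_Gs,
    alpha0,
    eta0,
    w0,
    X0,
    zeta0,
    zeta_cap,
):
    """Run one adaptive Metropolis-within-Gibbs chain.

    Returns thinned samples, per-block acceptance accounting (whole chain and
    final quarter), final tuning state and the final parameter state so a
    follow-on chain can be initialized from it.
    """
    np.random.seed(seed)
    K = eta0.shape[0]
    nblocks = 3 + 4 * K
    nfree = free_blocks.shape[0]

    alpha = alpha0.copy()
    eta = eta0.copy()
    w = w0.copy()
    X = X0.copy()

    D = np.empty((2 * K, 2 * K))
    F = np.empty((2 * K, 2 * K))
    F_prop = np.empty((2 * K, 2 * K))
    fill_distances(X, metric, D)
    fill_decay(D, alpha[1], alpha[2], F)

    free_eta = False
    free_w = False
    free_G = False
    free_Gs = False
    for b in free_blocks:
        if 3 <= b < 3 + K:
            free_eta = True
        elif 3 + K <= b < 3 + 2 * K:
            free_w = True
        elif 3 + 2 * K <= b < 3 + 3 * K:
            free_G = True
        elif 3 + 3 * K <= b:
            free_Gs = True
    # eta is free in every model variant; the flag mirrors free_blocks anyway.

    cur_lik = loglik_kernel(F, alpha[0], eta, w, inv_sbar, psi, U, Ldf)
    cur_prior = total_log_prior(
        alpha, eta, w, X, metric,
        a0_rate, a1_rate, a2_lo, a2_hi, eta_rate, w_beta_b,
        mu_G, sigma_G, mu_Gs, sigma_Gs,
        free_eta, free_w, free_G, free_Gs,
    )
    ok_init = np.isfinite(cur_lik) and np.isfinite(cur_prior)

    zeta = zeta0.copy()
    accept_counts = np.zeros(nblocks, dtype=np.int64)
    prop_counts = np.zeros(nblocks, dtype=np.int64)
    q_accept = np.zeros(nblocks, dtype=np.int64)
    q_prop = np.zeros(nblocks, dtype=np.int64)
    win_acc = np.zeros(nblocks, dtype=np.int64)
    win_prop = np.zeros(nblocks, dtype=np.int64)
    win_index = np.zeros(nblocks, dtype=np.int64)

    n_samples = n_iter // thin
    s_alpha = np.empty((n_samples, 3))
    s_eta = np.empty((n_samples, K))
    s_w = np.empty((n_samples, K))
    s_X = np.empty((n_samples, 2 * K, 2))
    s_lik = np.empty(n_samples)
    s_prior = np.empty(n_samples)
    s_iter = np.empty(n_samples, dtype=np.int64)

    old_row = np.empty(2 * K)
    old_drow = np.empty(2 * K)
    quarter_start = (3 * n_iter) // 4

    if not ok_init:
        n_iter = 0  # caller checks the flag; produce empty accounting

    for it in range(n_iter):
        b = free_blocks[np.random.randint(0, nfree)]
        step = np.exp(zeta[b])
        d_prior = 0.0
        new_lik = cur_lik
        accept = False
        rejected_early = False

        if b < 3:
            old = alpha[b]
            new = old + np.random.normal(0.0, step)
            if b == 0:
                d_prior = logp_exponential(new, a0_rate) - logp_exponential(
                    old, a0_rate
                )
            elif b == 1:
                d_prior = logp_exponential(new, a1_rate) - logp_exponential(
                    old, a1_rate
                )
            else:
                d_prior = logp_uniform(new, a2_lo, a2_hi) - logp_uniform(
                    old, a2_lo, a2_hi
                )
            if d_prior == -np.inf:
                rejected_early = True
            elif b == 0:
                new_lik = loglik_kernel(F, new, eta, w, inv_sbar, psi, U, Ldf)
            else:
                a1n = alpha[1]
                a2n = alpha[2]
                if b == 1:
                    a1n = new
                else:
                    a2n = new
                fill_decay(D, a1n, a2n, F_prop)
                new_lik = loglik_kernel(
                    F_prop, alpha[0], eta, w, inv_sbar, psi, U, Ldf
                )
            if not rejected_early:
                logr = (new_lik - cur_lik) + d_prior
                if np.log(np.random.random()) < logr:
                    accept = True
                    alpha[b] = new
                    if b > 0:
                        tmp = F
                        F = F_prop
                        F_prop = tmp
        elif b < 3 + K:
            k = b - 3
            old = eta[k]
            new = old + np.random.normal(0.0, step)
            d_prior = logp_exponential(new, eta_rate) - logp_exponential(
                old, eta_rate
            )
            if d_prior == -np.inf:
                rejected_early = True
            else:
                eta[k] = new
                new_lik = loglik_kernel(
                    F, alpha[0], eta, w, inv_sbar, psi, U, Ldf
                )
                logr = (new_lik - cur_lik) + d_prior
                if np.log(np.random.random()) < logr:
                    accept = True
                else:
                    eta[k] = old
        elif b < 3 + 2 * K:
            k = b - 3 - K
            old = w[k]
            new = old + np.random.normal(0.0, step)
            d_prior = logp_admixture(new, w_beta_b) - logp_admixture(
                old, w_beta_b
            )
            if d_prior == -np.inf:
                rejected_early = True
            else:
                w[k] = new
                new_lik = loglik_kernel(
                    F, alpha[0], eta, w, inv_sbar, psi, U, Ldf
                )
                logr = (new_lik - cur_lik) + d_prior
                if np.log(np.random.random()) < logr:
                    accept = True
                else:
                    w[k] = old
        else:
            if b < 3 + 3 * K:
                r = b - 3 - 2 * K  # population location G_k -> row r
                mux = mu_G[r, 0]
                muy = mu_G[r, 1]
                sig = sigma_G
            else:
                r = K + (b - 3 - 3 * K)  # admixture source row
                mux = mu_Gs[0]
                muy = mu_Gs[1]
                sig = sigma_Gs
            ox = X[r, 0]
            oy = X[r, 1]
            if metric == 1:
                arc = np.abs(np.random.normal(0.0, step))
                bearing = np.random.random() * TWO_PI
                nx, ny = destination_point(ox, oy, bearing, arc)
            else:
                nx = ox + np.random.normal(0.0, step)
                ny = oy + np.random.normal(0.0, step)
            d_prior = logp_location(nx, ny, mux, muy, sig, metric) - \
                logp_location(ox, oy, mux, muy, sig, metric)
            # swap in the new row of D and F, keeping the old for rollback
            for j in range(2 * K):
                old_row[j] = F[r, j]
                old_drow[j] = D[r, j]
            X[r, 0] = nx
            X[r, 1] = ny
            for j in range(2 * K):
                if j == r:
                    D[r, r] = 0.0
                    F[r, r] = 1.0
                    continue
                d = pair_distance(nx, ny, X[j, 0], X[j, 1], metric)
                v = decay_value(d, alpha[1], alpha[2])
                D[r, j] = d
                D[j, r] = d
                F[r, j] = v
                F[j, r] = v
            new_lik = loglik_kernel(F, alpha[0], eta, w, inv_sbar, psi, U, Ldf)
            logr = (new_lik - cur_lik) + d_prior
            if np.log(np.random.random()) < logr:
                accept = True
            else:
                X[r, 0] = ox
                X[r, 1] = oy
                for j in range(2 * K):
                    F[r, j] = old_row[j]
                    F[j, r] = old_row[j]
                    D[r, j] = old_drow[j]
                    D[j, r] = old_drow[j]
                D[r, r] = 0.0
                F[r, r] = 1.0

        if accept:
            cur_lik = new_lik
            cur_prior += d_prior
            accept_counts[b] += 1
            win_acc[b] += 1
        prop_counts[b] += 1
        win_prop[b] += 1
        if it >= quarter_start:
            q_prop[b] += 1
            if accept:
                q_accept[b] += 1

        # adaptation window boundary: every `adapt_every` iterations, tune
        # each parameter that was proposed at least once in the window
        if adapt_on and (it + 1) % adapt_every == 0:
            for fb in free_blocks:
                if win_prop[fb] == 0:
                    continue
                win_index[fb] += 1
                rate = win_acc[fb] / win_prop[fb]
                a = adapt_amount(win_index[fb])
                if rate > 0.44:
                    zeta[fb] += a
                else:
                    zeta[fb] -= a
                if zeta[fb] > zeta_cap:
                    zeta[fb] = zeta_cap
                elif zeta[fb] < -zeta_cap:
                    zeta[fb] = -zeta_cap
                win_prop[fb] = 0
                win_acc[fb] = 0

        if (it + 1) % thin == 0:
            # refresh the incrementally tracked prior to kill rounding drift
            cur_prior = total_log_prior(
                alpha, eta, w, X, metric,
                a0_rate, a1_rate, a2_lo, a2_hi, eta_rate, w_beta_b,
                mu_G, sigma_G, mu_Gs, sigma_Gs,
                free_eta, free_w, free_G, free_Gs,
            )
            s = (it + 1) // thin - 1
            for i in range(3):
                s_alpha[s, i] = alpha[i]
            for k in range(K):
                s_eta[s, k] = eta[k]
                s_w[s, k] = w[k]
            for i in range(2 * K):
                s_X[s, i, 0] = X[i, 0]
                s_X[s, i, 1] = X[i, 1]
            s_lik[s] = cur_lik
            s_prior[s] = cur_prior
            s_iter[s] = it + 1

    return (
        ok_init,
        s_alpha,
        s_eta,
        s_w,
        s_X,
        s_lik,
        s_prior,
        s_iter,
        accept_counts,
        prop_counts,
        q_accept,
        q_prop,
        zeta,
        alpha,
        eta,
        w,
        X,
        cur_lik,
        cur_prior,
    )
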