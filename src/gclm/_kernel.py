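"""Numba-compiled numerical core: implied-moment MVN log-likelihood, log
posterior, and the preconditioned random-walk Metropolis loop.

Everything here operates on flat arrays prepared by
:mod:`gclm._compile`; the readable reference implementations live in
:mod:`gclm.sem` and :mod:`gclm.ml` and are tested for exact agreement with
these kernels.
"""

import numpy as np
from numba import njit

LOG2PI = 1.8378770664093454


@njit(cache=True)
def _chol(a):
    """Lower Cholesky factor with an explicit success flag (no exceptions)."""
    n = a.shape[0]
    L = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            s = a[i, j]
            for m in range(j):
                s -= L[i, m] * L[j, m]
            if i == j:
                if s <= 1e-300:
                    return L, False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return L, True


@njit(cache=True)
def _forward_solve(L, B):
    """Solve L X = B for lower-triangular L; B is (n, m)."""
    n, m = B.shape
    X = np.empty((n, m))
    for c in range(m):
        for i in range(n):
            s = B[i, c]
            for j in range(i):
                s -= L[i, j] * X[j, c]
            X[i, c] = s / L[i, i]
    return X


@njit(cache=True)
def loglik_kernel(phi, kT, n_lat,
                  b_rows, b_cols, b_phi, alpha_phi,
                  blk_off, blk_size, ch_ptr, ch_r, ch_c, ch_phi, ch_log,
                  S, ybar, N):
    """Sum over units of the MVN log-density at the model-implied moments.

    Uses the sufficient statistics ``ybar`` (sample mean) and ``S`` (sample
    covariance, ML normalisation) of ``N`` complete cases.  Returns -1e300
    for numerically invalid parameter values (the samplers treat this as a
    rejection, never a silent repair).
    """
    for i in range(phi.size):
        if not np.isfinite(phi[i]) or np.abs(phi[i]) > 60.0:
            return -1e300

    # structural matrix and intercepts
    B = np.zeros((n_lat, n_lat))
    for i in range(kT):
        B[i, kT + i] = 1.0
    for e in range(b_rows.size):
        B[b_rows[e], b_cols[e]] += phi[b_phi[e]]
    A = np.eye(n_lat) - B
    alpha = np.zeros(n_lat)
    for i in range(kT):
        alpha[i] = phi[alpha_phi[i]]

    # Psi from per-block Cholesky parameters (always PSD by construction)
    Psi = np.zeros((n_lat, n_lat))
    for b in range(blk_off.size):
        m = blk_size[b]
        off = blk_off[b]
        L = np.zeros((m, m))
        for e in range(ch_ptr[b], ch_ptr[b + 1]):
            v = phi[ch_phi[e]]
            if ch_log[e] == 1:
                v = np.exp(v)
            L[ch_r[e], ch_c[e]] = v
        Psi[off:off + m, off:off + m] = np.dot(L, np.ascontiguousarray(L.T))

    # reduced form, restricted to the observed block
    mu_full = np.linalg.solve(A, alpha)
    M1 = np.linalg.solve(A, Psi)
    Sig_full = np.linalg.solve(A, np.ascontiguousarray(M1.T))
    So = np.ascontiguousarray(Sig_full[:kT, :kT])
    So = 0.5 * (So + np.ascontiguousarray(So.T))

    Lc, ok = _chol(So)
    if not ok:
        return -1e300
    logdet = 0.0
    for i in range(kT):
        logdet += 2.0 * np.log(Lc[i, i])

    U = _forward_solve(Lc, S)                        # L^{-1} S
    V = _forward_solve(Lc, np.ascontiguousarray(U.T))  # L^{-1} S^T L^{-T}
    tr = 0.0
    for i in range(kT):
        tr += V[i, i]

    d = (ybar - mu_full[:kT]).reshape(kT, 1)
    w = _forward_solve(Lc, d)
    quad = 0.0
    for i in range(kT):
        quad += w[i, 0] * w[i, 0]

    return -0.5 * N * (kT * LOG2PI + logdet + tr + quad)


@njit(cache=True)
def logpost_kernel(theta,
                   phi_base, fill_phi, fill_theta,
                   kT, n_lat, b_rows, b_cols, b_phi, alpha_phi,
                   blk_off, blk_size, ch_ptr, ch_r, ch_c, ch_phi, ch_log,
                   S, ybar, N,
                   prior_prec, prior_mean, logsd_mask, hn_scale,
                   grp_ptr, grp_idx, grp_pptr, grp_prec):
    """Unnormalized log posterior on the sampling scale.

    Priors: independent normal terms (``prior_prec``/``prior_mean``; zero
    precision = no term), group MVN terms (the difference-prior
    parameterization), half-normal(hn_scale) with log-scale Jacobian on
    log-Cholesky diagonals.
    """
    phi = phi_base.copy()
    for e in range(fill_phi.size):
        phi[fill_phi[e]] = theta[fill_theta[e]]
    ll = loglik_kernel(phi, kT, n_lat, b_rows, b_cols, b_phi, alpha_phi,
                       blk_off, blk_size, ch_ptr, ch_r, ch_c, ch_phi, ch_log,
                       S, ybar, N)
    if ll < -1e299:
        return -1e300
    lp = ll
    for i in range(theta.size):
        if prior_prec[i] > 0.0:
            d = theta[i] - prior_mean[i]
            lp += -0.5 * prior_prec[i] * d * d
        if logsd_mask[i]:
            s = theta[i]
            lp += -np.exp(2.0 * s) / (2.0 * hn_scale * hn_scale) + s
    for g in range(grp_ptr.size - 1):
        lo = grp_ptr[g]
        hi = grp_ptr[g + 1]
        n = hi - lo
        p0 = grp_pptr[g]
        for a in range(n):
            ta = theta[grp_idx[lo + a]]
            for b in range(n):
                lp += -0.5 * ta * grp_prec[p0 + a * n + b] * theta[grp_idx[lo + b]]
    return lp


@njit(cache=True)
def metropolis_kernel(theta0, Lprop, n_burn, thin, n_keep, seed, adapt,
                      phi_base, fill_phi, fill_theta,
                      kT, n_lat, b_rows, b_cols, b_phi, alpha_phi,
                      blk_off, blk_size, ch_ptr, ch_r, ch_c, ch_phi, ch_log,
                      S, ybar, N,
                      prior_prec, prior_mean, logsd_mask, hn_scale,
                      grp_ptr, grp_idx, grp_pptr, grp_prec):
    """Adaptive random-walk Metropolis with a fixed preconditioner ``Lprop``.

    The global step scale is tuned to a 0.234 acceptance rate during
    ``n_burn`` iterations (Robbins-Monro) and then frozen; every ``thin``-th
    post-burn-in state is retained, ``n_keep`` in total.
    """
    np.random.seed(seed)
    d = theta0.size
    theta = theta0.copy()
    lp = logpost_kernel(theta, phi_base, fill_phi, fill_theta,
                        kT, n_lat, b_rows, b_cols, b_phi, alpha_phi,
                        blk_off, blk_size, ch_ptr, ch_r, ch_c, ch_phi, ch_log,
                        S, ybar, N,
                        prior_prec, prior_mean, logsd_mask, hn_scale,
                        grp_ptr, grp_idx, grp_pptr, grp_prec)
    log_s = 0.0
    draws = np.empty((n_keep, d))
    kept = 0
    n_total = n_burn + thin * n_keep
    n_acc = 0
    for it in range(n_total):
        z = np.random.standard_normal(d)
        prop = theta + np.exp(log_s) * np.dot(Lprop, z)
        lpp = logpost_kernel(prop, phi_base, fill_phi, fill_theta,
                             kT, n_lat, b_rows, b_cols, b_phi, alpha_phi,
                             blk_off, blk_size, ch_ptr, ch_r, ch_c, ch_phi, ch_log,
                             S, ybar, N,
                             prior_prec, prior_mean, logsd_mask, hn_scale,
                             grp_ptr, grp_idx, grp_pptr, grp_prec)
        a = lpp - lp
        if a > 0.0:
            acc_prob = 1.0
        else:
            acc_prob = np.exp(a)
        if np.log(np.random.random()) < a:
            theta = prop
            lp = lpp
            n_acc += 1
        if adapt and it < n_burn:
            g = 1.0 / (it + 1.0) ** 0.6
            log_s += g * (acc_prob - 0.234)
            if log_s < -10.0:
                log_s = -10.0
            elif log_s > 5.0:
                log_s = 5.0
        if it >= n_burn and (it - n_burn + 1) % thin == 0:
            draws[kept] = theta
            kept += 1
    return draws, n_acc / n_total, log_s
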