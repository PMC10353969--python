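"""Numba-compiled log-posterior + gradient kernel for the hurdle model.

This mirrors ``MigrationModel.logp_grad`` exactly — same parameter
packing, same priors, same censoring branches — as one flat kernel, and
is used automatically when numba is importable.  The pure-numpy
implementation remains the reference; a test pins the two paths to each
other at 1e-10 relative tolerance on random points.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is available in practice
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap(a[0]) if a and callable(a[0]) else wrap


LOG_2PI = float(np.log(2.0 * np.pi))
LOG_SQRT_2PI = 0.5 * LOG_2PI
LOG_HC_NORM = float(np.log(2.0 / np.pi))


@njit(cache=True)
def _log_ndtr(z):
    """log of the standard normal CDF, stable in the lower tail."""
    if z > -1.0:
        return np.log1p(-0.5 * math.erfc(z / np.sqrt(2.0)))
    if z > -37.0:
        return np.log(0.5 * math.erfc(-z / np.sqrt(2.0)))
    # asymptotic expansion: log phi(z) - log|z| + log(1 - 1/z^2 + 3/z^4)
    z2 = z * z
    return -0.5 * z2 - LOG_SQRT_2PI - np.log(-z) + np.log1p(-1.0 / z2 + 3.0 / (z2 * z2))


@njit(cache=True)
def _corr_forward(y, K, L, zf, omz, cp):
    """Fill L (Cholesky of a correlation matrix), tanh values and row
    cumulative products from unconstrained y; returns the LKJ(2) +
    Jacobian log-prior value."""
    idx = 0
    prior = 0.0
    for i in range(K):
        for j in range(K):
            L[i, j] = 0.0
            cp[i, j] = 1.0
    L[0, 0] = 1.0
    for i in range(1, K):
        ci = K - i - 3.0 + 2.0 * 2.0  # LKJ eta = 2
        run = 1.0
        for j in range(i):
            z = np.tanh(y[idx])
            zf[idx] = z
            o = 1.0 - z * z
            if o < 1e-300:
                o = 1e-300
            omz[idx] = o
            cp[i, j] = run
            L[i, j] = z * run
            run *= np.sqrt(o)
            a = 1.0 + 0.5 * (i - 1 - j) + 0.5 * ci
            prior += a * np.log(o)
            idx += 1
        cp[i, i] = run
        L[i, i] = run
    return prior


@njit(cache=True)
def _corr_backward(y, K, L, zf, omz, cp, gL, gy_out):
    """Accumulate into gy_out the gradient of (prior + sum(gL * L)) w.r.t. y;
    gL need only be valid on the lower triangle incl. the diagonal."""
    idx0 = 0
    for i in range(1, K):
        ci = K - i - 3.0 + 2.0 * 2.0
        # t_excl[j] = sum_{k>j, k<=i} gL[i,k] * L[i,k]
        t = gL[i, i] * L[i, i]
        for j in range(i - 1, -1, -1):
            k = idx0 + j
            gz = gL[i, j] * cp[i, j] - zf[k] / omz[k] * t
            a = 1.0 + 0.5 * (i - 1 - j) + 0.5 * ci
            gy_out[k] += gz * omz[k] - 2.0 * a * zf[k]
            t += gL[i, j] * L[i, j]
        idx0 += i


@njit(cache=True)
def _tri_solve_lower(L, b, K):
    for i in range(K):
        s = b[i]
        for j in range(i):
            s -= L[i, j] * b[j]
        b[i] = s / L[i, i]


@njit(cache=True)
def _tri_solve_upper_t(L, b, K):
    # solves L^T x = b in place
    for i in range(K - 1, -1, -1):
        s = b[i]
        for j in range(i + 1, K):
            s -= L[j, i] * b[j]
        b[i] = s / L[i, i]


@njit(cache=True)
def migration_logp_grad(theta, X, fam_idx, place_idx, status, log_d,
                        log_lo, log_hi, gamma_mean, nfam, nplace,
                        noncentered):
    dim = theta.shape[0]
    n, p = X.shape
    grad = np.zeros(dim)
    for i in range(dim):
        if not np.isfinite(theta[i]) or np.abs(theta[i]) > 100.0:
            return -np.inf, grad
    ncorr = p * (p - 1) // 2
    nhyp = p + ncorr
    o_beta = 0
    o_gamma = p
    o_hb = 2 * p
    o_hg = 2 * p + nhyp
    o_S = 2 * p + 2 * nhyp
    o_T = o_S + nfam
    o_U = o_T + nplace
    o_V = o_U + nfam
    o_ls = o_V + nplace  # ls_S, ls_T, ls_U, ls_V, ls_E

    logp = 0.0
    # --- correlation blocks for the two coefficient priors ---------------
    Lb = np.empty((p, p))
    zfb = np.empty(ncorr)
    omzb = np.empty(ncorr)
    cpb = np.empty((p, p))
    logp += _corr_forward(theta[o_hb + p:o_hb + nhyp], p, Lb, zfb, omzb, cpb)
    Lg = np.empty((p, p))
    zfg = np.empty(ncorr)
    omzg = np.empty(ncorr)
    cpg = np.empty((p, p))
    logp += _corr_forward(theta[o_hg + p:o_hg + nhyp], p, Lg, zfg, omzg, cpg)
    tau_b = np.exp(theta[o_hb:o_hb + p])
    tau_g = np.exp(theta[o_hg:o_hg + p])

    beta = np.empty(p)
    gamma = np.empty(p)
    if noncentered:
        for i in range(p):
            sb = 0.0
            sg = 0.0
            for j in range(i + 1):
                sb += Lb[i, j] * theta[o_beta + j]
                sg += Lg[i, j] * theta[o_gamma + j]
            beta[i] = tau_b[i] * sb
            gamma[i] = gamma_mean[i] + tau_g[i] * sg
    else:
        for i in range(p):
            beta[i] = theta[o_beta + i]
            gamma[i] = theta[o_gamma + i]

    sS = np.exp(theta[o_ls])
    sT = np.exp(theta[o_ls + 1])
    sU = np.exp(theta[o_ls + 2])
    sV = np.exp(theta[o_ls + 3])
    sE = np.exp(theta[o_ls + 4])

    gbeta = np.zeros(p)
    ggamma = np.zeros(p)
    g_lsS = 0.0
    g_lsT = 0.0
    g_lsU = 0.0
    g_lsV = 0.0
    g_lsE = 0.0

    # --- likelihood -------------------------------------------------------
    for i in range(n):
        fi = fam_idx[i]
        bi = place_idx[i]
        eta = sS * theta[o_S + fi] + sT * theta[o_T + bi]
        mu = sU * theta[o_U + fi] + sV * theta[o_V + bi]
        for j in range(p):
            eta += X[i, j] * beta[j]
            mu += X[i, j] * gamma[j]
        # logistic pieces
        if eta > 0.0:
            log1pe = eta + np.log1p(np.exp(-eta))
        else:
            log1pe = np.log1p(np.exp(eta))
        pi = 1.0 / (1.0 + np.exp(-eta))
        logpi = eta - log1pe
        log1mpi = -log1pe

        st = status[i]
        gEta = 0.0
        gMu = 0.0
        if st == 0:  # observed, d = 0
            logp += log1mpi
            gEta = -pi
        elif st == 1:  # observed, d > 0
            z = (log_d[i] - mu) / sE
            logp += logpi - log_d[i] - np.log(sE) - 0.5 * z * z - LOG_SQRT_2PI
            gEta = 1.0 - pi
            gMu = z / sE
            g_lsE += -1.0 + z * z
        elif st == 2:  # interval censored, migrant (log_lo = -inf when d_min = 0)
            zb = (log_hi[i] - mu) / sE
            lb = _log_ndtr(zb)
            gb = np.exp(-0.5 * zb * zb - LOG_SQRT_2PI)
            if log_lo[i] == -np.inf:
                logdiff = lb
                ga_term = 0.0
                ga = 0.0
            else:
                za = (log_lo[i] - mu) / sE
                la = _log_ndtr(za)
                dd = la - lb
                if dd > -1e-12:
                    dd = -1e-12
                logdiff = lb + np.log1p(-np.exp(dd))
                ga = np.exp(-0.5 * za * za - LOG_SQRT_2PI - logdiff)
                ga_term = ga * za
            gb = gb * np.exp(-logdiff)
            logp += logpi + logdiff
            gEta = 1.0 - pi
            gMu = (ga - gb) / sE
            g_lsE += ga_term - gb * zb
        else:  # latent migration status, d <= d_max
            zb = (log_hi[i] - mu) / sE
            lb = _log_ndtr(zb)
            t1 = log1mpi
            t2 = logpi + lb
            if t1 > t2:
                ll = t1 + np.log1p(np.exp(t2 - t1))
            else:
                ll = t2 + np.log1p(np.exp(t1 - t2))
            logp += ll
            A = np.exp(ll)
            Phi_b = np.exp(lb)
            phi_b = np.exp(-0.5 * zb * zb - LOG_SQRT_2PI)
            gEta = pi * (1.0 - pi) * (Phi_b - 1.0) / A
            gMu = -pi * phi_b / (sE * A)
            g_lsE += -pi * phi_b * zb / A

        for j in range(p):
            gbeta[j] += gEta * X[i, j]
            ggamma[j] += gMu * X[i, j]
        grad[o_S + fi] += sS * gEta
        grad[o_T + bi] += sT * gEta
        grad[o_U + fi] += sU * gMu
        grad[o_V + bi] += sV * gMu
        g_lsS += sS * gEta * theta[o_S + fi]
        g_lsT += sT * gEta * theta[o_T + bi]
        g_lsU += sU * gMu * theta[o_U + fi]
        g_lsV += sV * gMu * theta[o_V + bi]

    grad[o_ls] += g_lsS
    grad[o_ls + 1] += g_lsT
    grad[o_ls + 2] += g_lsU
    grad[o_ls + 3] += g_lsV
    grad[o_ls + 4] += g_lsE

    # --- coefficient priors ----------------------------------------------
    gLb = np.zeros((p, p))
    gLg = np.zeros((p, p))
    gtau_b = np.zeros(p)
    gtau_g = np.zeros(p)
    if noncentered:
        # beta = diag(tau) L raw (+ mean); raw ~ N(0, I)
        for blk in range(2):
            if blk == 0:
                o_raw, tau, Lm, gLm, gtau = o_beta, tau_b, Lb, gLb, gtau_b
                g_eff = gbeta
            else:
                o_raw, tau, Lm, gLm, gtau = o_gamma, tau_g, Lg, gLg, gtau_g
                g_eff = ggamma
            for i in range(p):
                r = theta[o_raw + i]
                logp += -0.5 * r * r - 0.5 * LOG_2PI
                grad[o_raw + i] += -r
            for i in range(p):
                gA_row = g_eff[i]  # dlogp/d beta_i
                for j in range(i + 1):
                    # A = diag(tau) L ; beta_i = tau_i sum_j L_ij raw_j
                    grad[o_raw + j] += tau[i] * Lm[i, j] * gA_row
                    gLm[i, j] += gA_row * tau[i] * theta[o_raw + j]
                    gtau[i] += gA_row * Lm[i, j] * theta[o_raw + j]
    else:
        # centered MVN(mean, diag(tau) L L' diag(tau))
        for blk in range(2):
            if blk == 0:
                o_x, tau, Lm, gLm, gtau = o_beta, tau_b, Lb, gLb, gtau_b
                mean = np.zeros(p)
                g_eff = gbeta
            else:
                o_x, tau, Lm, gLm, gtau = o_gamma, tau_g, Lg, gLg, gtau_g
                mean = gamma_mean
                g_eff = ggamma
            for i in range(p):
                grad[o_x + i] += g_eff[i]  # likelihood chain
            u = np.empty(p)
            for i in range(p):
                u[i] = (theta[o_x + i] - mean[i]) / tau[i]
            v = u.copy()
            _tri_solve_lower(Lm, v, p)
            w = v.copy()
            _tri_solve_upper_t(Lm, w, p)
            vv = 0.0
            for i in range(p):
                vv += v[i] * v[i]
                logp += -np.log(tau[i]) - np.log(Lm[i, i])
                grad[o_x + i] += -w[i] / tau[i]
                gtau[i] += w[i] * (theta[o_x + i] - mean[i]) / (tau[i] * tau[i]) - 1.0 / tau[i]
            logp += -0.5 * vv - 0.5 * p * LOG_2PI
            for i in range(p):
                for j in range(i + 1):
                    gLm[i, j] += w[i] * v[j]
                gLm[i, i] -= 1.0 / Lm[i, i]

    # hyper scales: half-Cauchy(0,1) on tau = exp(ls), with Jacobian
    for i in range(p):
        for blk in range(2):
            if blk == 0:
                o_h, tau, gtau = o_hb, tau_b, gtau_b
            else:
                o_h, tau, gtau = o_hg, tau_g, gtau_g
            ls = theta[o_h + i]
            if ls > 0.0:
                lse = 2.0 * ls + np.log1p(np.exp(-2.0 * ls))
            else:
                lse = np.log1p(np.exp(2.0 * ls))
            logp += LOG_HC_NORM - lse + ls
            grad[o_h + i] += -np.tanh(ls) + gtau[i] * tau[i]
    _corr_backward(theta[o_hb + p:o_hb + nhyp], p, Lb, zfb, omzb, cpb, gLb,
                   grad[o_hb + p:o_hb + nhyp])
    _corr_backward(theta[o_hg + p:o_hg + nhyp], p, Lg, zfg, omzg, cpg, gLg,
                   grad[o_hg + p:o_hg + nhyp])

    # --- group intercept priors (non-centered raws) and scale priors ------
    for k in range(o_S, o_ls):
        r = theta[k]
        logp += -0.5 * r * r - 0.5 * LOG_2PI
        grad[k] += -r
    for k in range(o_ls, o_ls + 5):
        ls = theta[k]
        if ls > 0.0:
            lse = 2.0 * ls + np.log1p(np.exp(-2.0 * ls))
        else:
            lse = np.log1p(np.exp(2.0 * ls))
        logp += LOG_HC_NORM - lse + ls
        grad[k] += -np.tanh(ls)
    return logp, grad
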