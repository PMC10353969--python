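"""A no-U-turn sampler over an unconstrained log-density with gradient.

This is the default backend behind the fitting interface: dynamic
Hamiltonian Monte Carlo with slice-based trajectory sampling
(Hoffman & Gelman's NUTS), dual-averaging step-size adaptation towards a
target acceptance statistic, and windowed diagonal mass-matrix
adaptation during warmup.  The contract is asymptotically correct
samples from the supplied log-posterior; any backend honouring that
contract can replace it.
"""

from __future__ import annotations

import numpy as np

MAX_TREEDEPTH = 10
DELTA_MAX = 1000.0


def _joint(logp, p, m_inv):
    return logp - 0.5 * float(np.sum(p * p * m_inv))


class _Tree:
    __slots__ = ("lg",)

    def __init__(self, logp_grad):
        self.lg = logp_grad

    def leapfrog(self, q, p, grad, eps, m_inv):
        p = p + 0.5 * eps * grad
        q = q + eps * (m_inv * p)
        logp, grad = self.lg(q)
        p = p + 0.5 * eps * grad
        return q, p, grad, logp

    def build(self, q, p, grad, logu, v, j, eps, m_inv, joint0, rng):
        """Recursive doubling; returns a dict describing the subtree."""
        if j == 0:
            q1, p1, grad1, logp1 = self.leapfrog(q, p, grad, v * eps, m_inv)
            joint = _joint(logp1, p1, m_inv) if np.isfinite(logp1) else -np.inf
            n1 = int(logu <= joint)
            div = not (logu < joint + DELTA_MAX)
            alpha = min(1.0, np.exp(min(joint - joint0, 0.0))) if np.isfinite(joint) else 0.0
            return dict(qm=q1, pm=p1, gm=grad1,
                        qp=q1, pp=p1, gp=grad1,
                        qprop=q1, gprop=grad1, lprop=logp1,
                        n=n1, s=int(not div), div=div, alpha=alpha, nalpha=1)
        t1 = self.build(q, p, grad, logu, v, j - 1, eps, m_inv, joint0, rng)
        if t1["s"]:
            if v == -1:
                t2 = self.build(t1["qm"], t1["pm"], t1["gm"],
                                logu, v, j - 1, eps, m_inv, joint0, rng)
                t1["qm"], t1["pm"], t1["gm"] = t2["qm"], t2["pm"], t2["gm"]
            else:
                t2 = self.build(t1["qp"], t1["pp"], t1["gp"],
                                logu, v, j - 1, eps, m_inv, joint0, rng)
                t1["qp"], t1["pp"], t1["gp"] = t2["qp"], t2["pp"], t2["gp"]
            ntot = t1["n"] + t2["n"]
            if t2["n"] and rng.random() < t2["n"] / max(ntot, 1):
                t1["qprop"], t1["gprop"], t1["lprop"] = t2["qprop"], t2["gprop"], t2["lprop"]
            dq = t1["qp"] - t1["qm"]
            nou = (float(dq @ (m_inv * t1["pm"])) >= 0.0
                   and float(dq @ (m_inv * t1["pp"])) >= 0.0)
            t1["s"] = t2["s"] and int(nou)
            t1["div"] = t1["div"] or t2["div"]
            t1["n"] = ntot
            t1["alpha"] += t2["alpha"]
            t1["nalpha"] += t2["nalpha"]
        return t1


def _find_reasonable_eps(lg, q, grad, logp, m_inv, rng):
    eps = 1.0
    p = rng.standard_normal(len(q)) / np.sqrt(m_inv)
    tree = _Tree(lg)
    joint0 = _joint(logp, p, m_inv)
    _, p1, _, logp1 = tree.leapfrog(q, p, grad, eps, m_inv)
    joint1 = _joint(logp1, p1, m_inv) if np.isfinite(logp1) else -np.inf
    a = 1.0 if joint1 - joint0 > np.log(0.5) else -1.0
    for _ in range(60):
        eps *= 2.0 ** a
        _, p1, _, logp1 = tree.leapfrog(q, p, grad, eps, m_inv)
        joint1 = _joint(logp1, p1, m_inv) if np.isfinite(logp1) else -np.inf
        if a * (joint1 - joint0) <= a * np.log(0.5):
            break
    return eps


def _adapt_windows(warmup):
    """End iterations of the slow (mass-matrix) windows, Stan-style."""
    init_buf = max(15, int(0.15 * warmup))
    term_buf = max(10, int(0.10 * warmup))
    slow = warmup - init_buf - term_buf
    ends = []
    if slow > 20:
        w = max(15, slow // 7)
        pos = init_buf
        while pos < init_buf + slow:
            end = min(pos + w, init_buf + slow)
            if init_buf + slow - end < w:  # absorb a short trailing window
                end = init_buf + slow
            ends.append(end)
            pos = end
            w *= 2
    return ends, init_buf


def nuts_sample(logp_grad, dim, rng, draws=500, warmup=500, initial=None,
                target_accept=0.85, max_treedepth=MAX_TREEDEPTH, m_inv0=None,
                eps0=None):
    """Run one NUTS chain; returns (draws array, stats dict).

    ``m_inv0`` seeds the diagonal inverse mass matrix (e.g. from curvature
    at the mode) and ``eps0`` the step size; windowed adaptation refines
    both during warmup.
    """
    q = np.zeros(dim) if initial is None else np.array(initial, float)
    logp, grad = logp_grad(q)
    if not np.isfinite(logp):
        raise ValueError("log-posterior not finite at the initial point")
    m_inv = np.ones(dim) if m_inv0 is None else np.asarray(m_inv0, float)
    tree = _Tree(logp_grad)

    eps = float(eps0) if eps0 else _find_reasonable_eps(logp_grad, q, grad, logp, m_inv, rng)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = np.log(eps), 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0

    window_ends, init_buf = _adapt_windows(warmup)
    wf_n, wf_m, wf_s = 0, np.zeros(dim), np.zeros(dim)

    out = np.empty((draws, dim))
    divergences = 0
    depths = np.zeros(draws, int)
    accept_stats = []

    for it in range(warmup + draws):
        p0 = rng.standard_normal(dim) / np.sqrt(m_inv)
        joint0 = _joint(logp, p0, m_inv)
        logu = joint0 - rng.exponential()
        qm = qp = q
        pm = pp = p0
        gm = gp = grad
        qprop, gprop, lprop = q, grad, logp
        j, n = 0, 1
        alpha_sum, nalpha = 0.0, 0
        diverged = False
        while j < max_treedepth:
            v = 1 if rng.random() < 0.5 else -1
            if v == -1:
                t = tree.build(qm, pm, gm, logu, v, j, eps, m_inv, joint0, rng)
                qm, pm, gm = t["qm"], t["pm"], t["gm"]
            else:
                t = tree.build(qp, pp, gp, logu, v, j, eps, m_inv, joint0, rng)
                qp, pp, gp = t["qp"], t["pp"], t["gp"]
            if t["s"] and t["n"] and rng.random() < min(1.0, t["n"] / n):
                qprop, gprop, lprop = t["qprop"], t["gprop"], t["lprop"]
            n += t["n"]
            alpha_sum += t["alpha"]
            nalpha += t["nalpha"]
            diverged = diverged or t["div"]
            if not t["s"]:
                break
            dq = qp - qm
            if (float(dq @ (m_inv * pm)) < 0.0 or float(dq @ (m_inv * pp)) < 0.0):
                break
            j += 1
        q, grad, logp = qprop, gprop, lprop
        accept = alpha_sum / max(nalpha, 1)

        if it < warmup:
            da_count += 1
            h_bar = ((1.0 - 1.0 / (da_count + t0)) * h_bar
                     + (target_accept - accept) / (da_count + t0))
            log_eps = mu - np.sqrt(da_count) / gamma * h_bar
            w = da_count ** (-kappa)
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if window_ends and it >= init_buf:
                wf_n += 1
                dlt = q - wf_m
                wf_m += dlt / wf_n
                wf_s += dlt * (q - wf_m)
                if it + 1 == window_ends[0]:
                    window_ends.pop(0)
                    if wf_n > 2:
                        var = wf_s / (wf_n - 1)
                        m_inv = (wf_n / (wf_n + 5.0)) * var + 1e-3 * (5.0 / (wf_n + 5.0))
                    wf_n, wf_m, wf_s = 0, np.zeros(dim), np.zeros(dim)
                    # metric changed: restart dual averaging around the
                    # current step size rather than re-searching
                    mu = np.log(10.0 * eps)
                    log_eps_bar, h_bar, da_count = np.log(eps), 0.0, 0
            if it + 1 == warmup:
                eps = float(np.exp(log_eps_bar))
        else:
            k = it - warmup
            out[k] = q
            depths[k] = j
            if diverged:
                divergences += 1
            accept_stats.append(accept)

    stats = dict(divergences=divergences, step_size=eps,
                 mean_accept=float(np.mean(accept_stats)) if accept_stats else np.nan,
                 mean_treedepth=float(np.mean(depths)) if draws else np.nan,
                 m_inv=m_inv)
    return out, stats
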