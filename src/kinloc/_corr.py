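"""Unconstrained parameterization of correlation matrices and MVN priors.

Both models place hierarchical multivariate Gaussian priors on their
coefficient vectors, with the covariance decomposed into a vector of
scales (half-Cauchy(0,1) priors) and a correlation matrix with a
Lewandowski-Kurowicka-Joe prior of shape ``eta`` (default 2).  The
correlation matrix is parameterized through the canonical partial
correlations of its Cholesky factor: free entry (i,j) is z_ij = tanh(y_ij)
scaled by the remaining row norm, which factorizes as

    L_ij = z_ij * prod_{k<j} sqrt(1 - z_ik^2),    L_ii = prod_{k<i} sqrt(1 - z_ik^2)

so rows are unit vectors by construction and the transform, its
log-Jacobian and the LKJ density (which reduce to
sum a_ij * log(1 - z_ij^2)) evaluate as a handful of whole-matrix
cumulative products.  Gradients are exact reverse-mode expressions,
verified against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

LOG_2PI = float(np.log(2.0 * np.pi))


def corr_free_dim(K: int) -> int:
    return K * (K - 1) // 2


class _CorrTransform:
    """Cached whole-matrix machinery for one (K, eta)."""

    _cache: dict = {}

    def __new__(cls, K: int, eta: float = 2.0):
        key = (K, float(eta))
        if key not in cls._cache:
            self = super().__new__(cls)
            self.K, self.eta = K, float(eta)
            self.rows, self.cols = np.tril_indices(K, -1)  # row-major free entries
            i = np.arange(K)[:, None]
            j = np.arange(K)[None, :]
            ci = K - i - 3.0 + 2.0 * eta          # LKJ exponent of L_ii, 0-based rows
            a = 1.0 + 0.5 * (i - 1 - j) + 0.5 * ci
            self.a_free = a[self.rows, self.cols]
            cls._cache[key] = self
        return cls._cache[key]

    def _forward_cache(self, y):
        K = self.K
        Z = np.zeros((K, K))
        zf = np.tanh(y)
        Z[self.rows, self.cols] = zf
        one_m_z2 = 1.0 - zf * zf
        M = np.ones((K, K))
        M[self.rows, self.cols] = np.sqrt(one_m_z2)
        cp = np.ones((K, K))
        cp[:, 1:] = np.cumprod(M[:, :-1], axis=1)  # cp[i,j] = prod_{k<j} M[i,k]
        L = Z * cp
        np.fill_diagonal(L, np.diag(cp))  # cp_ii = prod_{k<i} M[i,k]
        return L, Z, zf, one_m_z2, cp

    def forward(self, y):
        return self._forward_cache(y)[0]

    def with_prior_grad(self, y, gL_ext, cache=None):
        # gL_ext need only be valid on the lower triangle incl. diagonal
        L, Z, zf, one_m_z2, cp = cache if cache is not None else self._forward_cache(y)
        prior = float(self.a_free @ np.log(np.maximum(one_m_z2, 1e-300)))
        # reverse sweep: t_ij = sum_{k>j} gL_ik L_ik (incl. diagonal);
        # L's upper triangle is zero, so the product is already masked
        P = gL_ext * L
        T = np.cumsum(P[:, ::-1], axis=1)[:, ::-1]
        t_excl = T - P
        gz = (gL_ext * cp)[self.rows, self.cols] \
            - zf / np.maximum(one_m_z2, 1e-300) * t_excl[self.rows, self.cols]
        gy = gz * one_m_z2 - 2.0 * self.a_free * zf
        return L, prior, gy


def corr_chol(y: np.ndarray, K: int) -> np.ndarray:
    """Cholesky factor of a correlation matrix from unconstrained ``y``."""
    return _CorrTransform(K).forward(np.asarray(y, float))


def corr_chol_with_prior_grad(y: np.ndarray, K: int, gL_ext: np.ndarray,
                              eta: float = 2.0):
    """Forward + reverse sweep through the correlation parameterization.

    Returns ``(L, prior_logp, gy)`` where ``prior_logp`` is the LKJ(eta)
    log-density of L plus the log-Jacobian of the unconstrained
    transform, and ``gy`` is the gradient w.r.t. ``y`` of
    ``prior_logp + sum(tril(gL_ext) * L)``.
    """
    return _CorrTransform(K, eta).with_prior_grad(np.asarray(y, float), gL_ext)


def half_cauchy_logp_grad(ls: np.ndarray):
    """log half-Cauchy(0,1) density of sigma=exp(ls) plus log-Jacobian.

    Returns (logp, dlogp/dls), elementwise over ``ls``.
    """
    ls = np.asarray(ls, float)
    logp = np.log(2.0 / np.pi) - np.logaddexp(0.0, 2.0 * ls) + ls
    grad = -np.tanh(ls)  # 1 - 2*sigma^2/(1+sigma^2)
    return logp, grad


def _tri_solve(L, b, trans=False):
    from scipy.linalg import solve_triangular
    return solve_triangular(L.T if trans else L, b, lower=not trans,
                            check_finite=False)


def mvn_chol_logp_grads(x: np.ndarray, mean: np.ndarray, tau: np.ndarray,
                        L: np.ndarray):
    """MVN(mean, diag(tau) L L' diag(tau)) log-density and gradients.

    Returns ``(logp, gx, gtau, gL)`` with gL valid on the lower triangle
    (including the diagonal).
    """
    p = len(x)
    u = (x - mean) / tau
    v = _tri_solve(L, u)
    w = _tri_solve(L, v, trans=True)
    logp = (-0.5 * float(v @ v) - float(np.sum(np.log(tau)))
            - float(np.sum(np.log(np.diag(L)))) - 0.5 * p * LOG_2PI)
    gx = -w / tau
    gtau = w * (x - mean) / tau ** 2 - 1.0 / tau
    gL = np.outer(w, v)
    gL[np.diag_indices(p)] -= 1.0 / np.diag(L)
    return logp, gx, gtau, gL


class HierCovPrior:
    """Hierarchical covariance block: scales (half-Cauchy) + LKJ correlation.

    Owns ``K + K(K-1)/2`` unconstrained parameters (log-scales then
    correlation free parameters).  Used centered (MVN prior on a
    coefficient vector) or non-centered (A = diag(tau) L maps standard
    normal rows to correlated group intercepts).
    """

    def __init__(self, K: int, eta: float = 2.0):
        self.K = K
        self.eta = eta
        self.nfree = K + corr_free_dim(K)
        self._tf = _CorrTransform(K, eta)

    def split(self, theta_block: np.ndarray):
        return theta_block[: self.K], theta_block[self.K:]

    def matrices(self, theta_block: np.ndarray, with_cache: bool = False):
        ls, y = self.split(theta_block)
        cache = self._tf._forward_cache(y)
        if with_cache:
            return np.exp(ls), cache[0], cache
        return np.exp(ls), cache[0]

    def logp_grad(self, theta_block: np.ndarray, gtau_ext: np.ndarray,
                  gL_ext: np.ndarray, cache=None):
        """Hyperprior value and gradient, folding in external dependences.

        ``gtau_ext``/``gL_ext`` are gradients of the rest of the model
        (likelihood, MVN of coefficients) w.r.t. tau and L; ``cache`` may
        carry the forward pass from a prior ``matrices`` call.
        """
        ls, y = self.split(theta_block)
        tau = np.exp(ls)
        hc_val, hc_grad = half_cauchy_logp_grad(ls)
        L, corr_prior, gy = self._tf.with_prior_grad(y, gL_ext, cache=cache)
        gls = hc_grad + gtau_ext * tau
        return float(np.sum(hc_val)) + corr_prior, np.concatenate([gls, gy])

    def mvn_with_hyperprior(self, x, mean, theta_block):
        """logp and grads of MVN(x; mean, Sigma(theta)) + hyperpriors.

        Returns (logp, gx, gtheta_block).
        """
        ls, y = self.split(theta_block)
        tau = np.exp(ls)
        hc_val, hc_grad = half_cauchy_logp_grad(ls)
        cache = self._tf._forward_cache(y)
        lp_mvn, gx, gtau, gL = mvn_chol_logp_grads(x, mean, tau, cache[0])
        _, corr_prior, gy = self._tf.with_prior_grad(y, gL, cache=cache)
        gls = hc_grad + gtau * tau
        logp = lp_mvn + float(np.sum(hc_val)) + corr_prior
        return logp, gx, np.concatenate([gls, gy])
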