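"""Hierarchical two-part (hurdle) model of intergenerational migration.

An individual either stays (probability 1 - pi) or migrates a distance
d > 0 drawn from a log-normal density g.  Both parts share a covariate
vector and carry crossed varying intercepts for the extended family and
for the (child-side) birthplace:

    logit(pi_i) = x_i' beta + S_l(i) + T_b(i)
    log(d_i)    = x_i' gamma + U_l(i) + V_b(i) + E_i,   E_i ~ N(0, sigma_E)

Censored dyads contribute CDF-difference terms; dyads where the
migration indicator itself is latent (mover's region contains the anchor
place) contribute the marginal (1-pi) + pi*Phi((log d_max - mu)/sigma_E).

Priors: beta ~ MVN(0, Sigma_beta) and gamma ~ MVN((log 100, 0, ...),
Sigma_gamma), each covariance decomposed into half-Cauchy(0,1) scales
and an LKJ(2) correlation; S, T, U, V ~ N(0, sigma) with half-Cauchy(0,1)
scales; sigma_E ~ half-Cauchy(0,1).  The prior baseline log(100) makes
100 km the central prior migration distance.  Group intercepts are
sampled non-centered (raw standard normals scaled inside the model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log_ndtr

from ._corr import LOG_2PI, HierCovPrior, half_cauchy_logp_grad
from .outcomes import MigrationOutcome

VARIANTS = ("baseline", "settlement_size", "ancestry")
REF_SEX = "female"
REF_GENERATION = "grandparent"
SETTLEMENT_DUMMIES = ("town", "farm", "unknown")  # reference: city

_SQ2PI = float(np.sqrt(2.0 * np.pi))


def ancestry_covariates(proportions, eps: float = 1e-3):
    """Additive log-ratio ancestry covariates.

    ``proportions`` is (khoesan, west_african, eurasian), each >= 0 and
    summing to 1; components are floored at ``eps`` and renormalized so a
    degenerate simplex still yields finite log-ratios.  Returns
    (log(khoesan/eurasian), log(west_african/eurasian)).
    """
    p = np.asarray(proportions, float)
    if np.any(p < 0):
        raise ValueError("ancestry proportions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("ancestry proportions must sum to 1")
    p = np.maximum(p, eps)
    p = p / p.sum()
    return float(np.log(p[0] / p[2])), float(np.log(p[1] / p[2]))


@dataclass
class MigrationDesign:
    """Covariates, group indices and outcome data aligned row-by-row."""

    X: np.ndarray
    colnames: list
    fam_idx: np.ndarray
    place_idx: np.ndarray
    fam_ids: list
    place_ids: list
    status: np.ndarray       # 0 zero, 1 positive, 2 interval, 3 latent-status
    d: np.ndarray            # observed distance (rows with status 1)
    log_lo: np.ndarray       # log d_min (rows with status 2)
    log_hi: np.ndarray       # log d_max (rows with status 2 or 3)
    ref_year: float
    variant: str
    outcomes: list = field(repr=False, default_factory=list)

    @property
    def n(self):
        return self.X.shape[0]

    @property
    def p(self):
        return self.X.shape[1]


def _region_dummy(regions, all_regions):
    """Map region labels to a 0/1 dummy; the alphabetically first level
    (over all gazetteer regions, observed or not) is the reference."""
    levels = sorted(set(all_regions))
    if len(levels) > 2:
        raise ValueError(f"expected at most two regions, got {levels}")
    ref = levels[0]
    other = levels[1] if len(levels) > 1 else "alt"
    return ref, other, np.array([0.0 if r == ref else 1.0 for r in regions])


def build_migration_design(outcomes, families, gazetteer, variant="baseline",
                           ref_year=None, ancestry_eps=1e-3,
                           birth_year_source="proband"):
    """Design matrix + indices for non-missing migration outcomes.

    The factorial part is sex x generation x region with references
    female / grandparent / alphabetically-first region (cederberg in the
    synthetic gazetteers); birth year is the proband's (default),
    centered at the sample median and scaled to decades.  ``birth_year_source="mover"`` uses the mover's own birth
    year where recorded, falling back to the proband's.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    rows = [o for o in outcomes if o.status != "missing"]
    if not rows:
        raise ValueError("no non-missing outcomes")
    fam_by_id = {f.family_id: f for f in families}

    years = {}
    for f in families:
        by = f.proband.birth_year
        years[f.family_id] = float(by) if by is not None else np.nan
    if ref_year is None:
        vals = np.array([y for y in years.values() if np.isfinite(y)])
        ref_year = float(np.median(vals)) if len(vals) else 0.0

    fam_ids = sorted({o.family_id for o in rows})
    place_ids = sorted({o.anchor_place for o in rows})
    fmap = {f: i for i, f in enumerate(fam_ids)}
    pmap = {p: i for i, p in enumerate(place_ids)}

    sex = np.array([1.0 if o.sex != REF_SEX else 0.0 for o in rows])
    gen = np.array([1.0 if o.generation != REF_GENERATION else 0.0 for o in rows])
    regions = [gazetteer[o.anchor_place].region for o in rows]
    all_regions = {b.region for b in gazetteer.values()}
    _, other, reg = _region_dummy(regions, all_regions)
    def _year(o):
        if birth_year_source == "mover":
            fam = fam_by_id.get(o.family_id)
            mover = fam.get(o.mover_role) if fam else None
            if mover is not None and mover.birth_year is not None:
                return float(mover.birth_year)
        return years.get(o.family_id, np.nan)

    byear = np.array([(_year(o) - ref_year) / 10.0 for o in rows])
    byear = np.where(np.isfinite(byear), byear, 0.0)

    cols = [np.ones(len(rows)), byear, sex, gen, reg,
            sex * gen, sex * reg, gen * reg, sex * gen * reg]
    rname = f"region_{other}"
    names = ["intercept", "birth_year_dec", "sex_male", "gen_parent", rname,
             "male_x_parent", f"male_x_{rname}", f"parent_x_{rname}",
             f"male_x_parent_x_{rname}"]

    if variant == "settlement_size":
        for s in SETTLEMENT_DUMMIES:
            col = np.array([
                1.0 if _mover_settlement(o, gazetteer) == s else 0.0 for o in rows
            ])
            cols.append(col)
            names.append(f"settlement_{s}")
    elif variant == "ancestry":
        alr = {}
        for fid in fam_ids:
            fam = fam_by_id.get(fid)
            if fam is None or fam.ancestry is None:
                raise ValueError(
                    "ancestry variant requires ancestry proportions for every family "
                    f"(missing for {fid!r})")
            alr[fid] = ancestry_covariates(fam.ancestry, ancestry_eps)
        cols.append(np.array([alr[o.family_id][0] for o in rows]))
        cols.append(np.array([alr[o.family_id][1] for o in rows]))
        names += ["alr_khoesan_eurasian", "alr_westafrican_eurasian"]

    X = np.column_stack(cols)
    code = {"observed": None, "interval_censored": 2, "status_unknown_censored": 3}
    status = np.empty(len(rows), int)
    d = np.zeros(len(rows))
    log_lo = np.zeros(len(rows))
    log_hi = np.zeros(len(rows))
    for i, o in enumerate(rows):
        if o.status == "observed":
            status[i] = 1 if o.d > 0 else 0
            d[i] = o.d
        else:
            status[i] = code[o.status]
            lo, hi = o.interval
            log_lo[i] = np.log(lo) if lo > 0 else -np.inf
            log_hi[i] = np.log(hi)
    return MigrationDesign(
        X=X, colnames=names,
        fam_idx=np.array([fmap[o.family_id] for o in rows], int),
        place_idx=np.array([pmap[o.anchor_place] for o in rows], int),
        fam_ids=fam_ids, place_ids=place_ids,
        status=status, d=d, log_lo=log_lo, log_hi=log_hi,
        ref_year=ref_year, variant=variant, outcomes=rows,
    )


def _mover_settlement(o: MigrationOutcome, gazetteer) -> str:
    if o.mover_place is not None:
        return gazetteer[o.mover_place].settlement_size
    return "unknown"


def _norm_logpdf(z):
    return -0.5 * z * z - 0.5 * LOG_2PI


def hurdle_logdensity(outcome: MigrationOutcome, eta: float, mu: float,
                      sigma_E: float) -> float:
    """Log-probability of one migration outcome under the hurdle model.

    ``eta`` is the log-odds of migration, ``mu`` the mean log-distance.
    Reference implementation for single outcomes; the model class uses a
    vectorized equivalent.
    """
    if sigma_E <= 0:
        raise ValueError("sigma_E must be positive")
    logpi = eta - np.logaddexp(0.0, eta)
    log1mpi = -np.logaddexp(0.0, eta)
    if outcome.status == "observed":
        if outcome.d == 0:
            return float(log1mpi)
        ld = np.log(outcome.d)
        return float(logpi - ld - np.log(sigma_E)
                     + _norm_logpdf((ld - mu) / sigma_E))
    lo, hi = outcome.interval
    if outcome.status == "interval_censored":
        if lo >= hi:
            raise ValueError("interval_censored requires d_min < d_max")
        if lo < 0:
            raise ValueError("interval_censored requires d_min >= 0")
        # lo == 0 (assume-migrated variant): the interval is (0, d_max]
        la = -np.inf if lo == 0 else log_ndtr((np.log(lo) - mu) / sigma_E)
        zb = (np.log(hi) - mu) / sigma_E
        lb = log_ndtr(zb)
        return float(logpi + lb + np.log1p(-np.exp(la - lb)))
    if outcome.status == "status_unknown_censored":
        if hi <= 0:
            raise ValueError("status_unknown_censored requires d_max > 0")
        zb = (np.log(hi) - mu) / sigma_E
        return float(np.logaddexp(log1mpi, logpi + log_ndtr(zb)))
    raise ValueError(f"cannot evaluate status {outcome.status!r}")


class MigrationModel:
    """Log-posterior (value + gradient) of the hurdle model on a design.

    Parameters are packed into one unconstrained vector; scales enter as
    logs and group intercepts as raw standard-normal deviates
    (non-centered), so the posterior is smooth over all of R^dim.
    """

    def __init__(self, design: MigrationDesign, lkj_eta: float = 2.0,
                 prior_distance_km: float = 100.0, coef_param: str = "centered"):
        """``coef_param`` selects the parameterization of the coefficient
        blocks under their hierarchical MVN priors: "centered" (sample beta,
        gamma directly; best when the likelihood pins them, i.e. large n) or
        "noncentered" (sample standard-normal deviates scaled through the
        prior Cholesky; best for small datasets where the prior dominates).
        Both describe the identical posterior."""
        if coef_param not in ("centered", "noncentered"):
            raise ValueError("coef_param must be 'centered' or 'noncentered'")
        self.coef_param = coef_param
        self.design = design
        d = design
        self.p = d.p
        self.nfam = len(d.fam_ids)
        self.nplace = len(d.place_ids)
        self.hyper_beta = HierCovPrior(self.p, lkj_eta)
        self.hyper_gamma = HierCovPrior(self.p, lkj_eta)
        self.gamma_mean = np.zeros(self.p)
        self.gamma_mean[0] = np.log(prior_distance_km)

        self.idx_zero = np.where(d.status == 0)[0]
        self.idx_pos = np.where(d.status == 1)[0]
        self.idx_int = np.where(d.status == 2)[0]
        self.idx_lat = np.where(d.status == 3)[0]
        self.log_d_pos = np.log(d.d[self.idx_pos]) if len(self.idx_pos) else np.zeros(0)

        sizes = {
            "beta": self.p, "gamma": self.p,
            "hyp_beta": self.hyper_beta.nfree, "hyp_gamma": self.hyper_gamma.nfree,
            "S_raw": self.nfam, "T_raw": self.nplace,
            "U_raw": self.nfam, "V_raw": self.nplace,
            "ls_S": 1, "ls_T": 1, "ls_U": 1, "ls_V": 1, "ls_E": 1,
        }
        self.slices, ofs = {}, 0
        for k, sz in sizes.items():
            self.slices[k] = slice(ofs, ofs + sz)
            ofs += sz
        self.dim = ofs

        # contiguous arrays for the compiled kernel
        from . import _fastmig
        self._fast = _fastmig if _fastmig.HAVE_NUMBA else None
        self._Xc = np.ascontiguousarray(d.X, dtype=np.float64)
        self._fam_c = np.ascontiguousarray(d.fam_idx, dtype=np.int64)
        self._place_c = np.ascontiguousarray(d.place_idx, dtype=np.int64)
        self._status_c = np.ascontiguousarray(d.status, dtype=np.int64)
        self._logd_c = np.where(d.d > 0, np.log(np.maximum(d.d, 1e-300)), 0.0)
        self._loglo_c = np.ascontiguousarray(d.log_lo, dtype=np.float64)
        self._loghi_c = np.ascontiguousarray(d.log_hi, dtype=np.float64)

    # -- packing helpers ---------------------------------------------------
    def unpack(self, theta):
        return {k: theta[s] for k, s in self.slices.items()}

    @property
    def param_names(self):
        names = []
        for k, s in self.slices.items():
            n = s.stop - s.start
            if k in ("beta", "gamma"):
                names += [f"{k}[{c}]" for c in self.design.colnames]
            elif n == 1:
                names.append(k)
            else:
                names += [f"{k}[{i}]" for i in range(n)]
        return names

    def initial_point(self, rng):
        theta = 0.01 * rng.standard_normal(self.dim)
        if self.coef_param == "centered":
            theta[self.slices["gamma"]][0] += self.gamma_mean[0]
        for k in ("ls_S", "ls_T", "ls_U", "ls_V", "ls_E"):
            theta[self.slices[k]] = -0.5 + 0.1 * rng.standard_normal(1)
        return theta

    # -- coefficient blocks ------------------------------------------------
    def _coefs(self, q):
        """Effective (beta, gamma) under either parameterization."""
        if self.coef_param == "centered":
            return q["beta"], q["gamma"], None
        info = {}
        out = {}
        for key, hkey, hyper, mean in (
            ("beta", "hyp_beta", self.hyper_beta, np.zeros(self.p)),
            ("gamma", "hyp_gamma", self.hyper_gamma, self.gamma_mean),
        ):
            tau, L, cache = hyper.matrices(q[hkey], with_cache=True)
            A = tau[:, None] * L
            out[key] = mean + A @ q[key]
            info[key] = (tau, L, A, cache)
        return out["beta"], out["gamma"], info

    def coef_draws(self, stacked):
        """Effective coefficient draws (S, p) per block from raw draws."""
        betas = np.empty((len(stacked), self.p))
        gammas = np.empty((len(stacked), self.p))
        for s, theta in enumerate(np.asarray(stacked)):
            q = self.unpack(theta)
            betas[s], gammas[s], _ = self._coefs(q)
        return {"beta": betas, "gamma": gammas}

    # -- linear predictors -------------------------------------------------
    def _linpreds(self, q):
        d = self.design
        beta, gamma, _ = self._coefs(q)
        sS, sT = np.exp(q["ls_S"][0]), np.exp(q["ls_T"][0])
        sU, sV = np.exp(q["ls_U"][0]), np.exp(q["ls_V"][0])
        eta = d.X @ beta + sS * q["S_raw"][d.fam_idx] + sT * q["T_raw"][d.place_idx]
        mu = d.X @ gamma + sU * q["U_raw"][d.fam_idx] + sV * q["V_raw"][d.place_idx]
        return eta, mu, (sS, sT, sU, sV)

    def pointwise_loglik(self, theta):
        """Per-outcome log-likelihood vector (retained for PSIS-LOO)."""
        q = self.unpack(theta)
        eta, mu, _ = self._linpreds(q)
        sE = np.exp(q["ls_E"][0])
        ll = np.empty(self.design.n)
        log1pe = np.logaddexp(0.0, eta)
        logpi, log1mpi = eta - log1pe, -log1pe
        iz, ip, ii, il = self.idx_zero, self.idx_pos, self.idx_int, self.idx_lat
        ll[iz] = log1mpi[iz]
        if len(ip):
            z = (self.log_d_pos - mu[ip]) / sE
            ll[ip] = logpi[ip] - self.log_d_pos - np.log(sE) + _norm_logpdf(z)
        if len(ii):
            za = (self.design.log_lo[ii] - mu[ii]) / sE
            zb = (self.design.log_hi[ii] - mu[ii]) / sE
            la, lb = log_ndtr(za), log_ndtr(zb)
            ll[ii] = logpi[ii] + lb + np.log1p(-np.exp(np.minimum(la - lb, -1e-12)))
        if len(il):
            zb = (self.design.log_hi[il] - mu[il]) / sE
            ll[il] = np.logaddexp(log1mpi[il], logpi[il] + log_ndtr(zb))
        return ll

    def loglik(self, theta):
        return float(np.sum(self.pointwise_loglik(theta)))

    # -- joint log-posterior with gradient ---------------------------------
    def logp_grad(self, theta):
        """Joint log-posterior and gradient; dispatches to the compiled
        kernel when numba is available (the numpy path is the reference
        implementation and the two are pinned together in the tests)."""
        if self._fast is not None:
            return self._fast.migration_logp_grad(
                np.ascontiguousarray(theta, np.float64), self._Xc,
                self._fam_c, self._place_c, self._status_c, self._logd_c,
                self._loglo_c, self._loghi_c, self.gamma_mean,
                self.nfam, self.nplace, self.coef_param == "noncentered")
        return self.logp_grad_py(theta)

    def logp_grad_py(self, theta):
        # reject absurd points before exp/erf overflow can produce NaNs;
        # divergent leapfrog excursions land here and are simply cut off
        if not np.all(np.isfinite(theta)) or np.max(np.abs(theta)) > 100.0:
            return -np.inf, np.zeros(self.dim)
        d = self.design
        q = self.unpack(theta)
        grad = np.zeros(self.dim)
        beta, gamma, ncinfo = self._coefs(q)
        sS, sT = np.exp(q["ls_S"][0]), np.exp(q["ls_T"][0])
        sU, sV = np.exp(q["ls_U"][0]), np.exp(q["ls_V"][0])
        eta = d.X @ beta + sS * q["S_raw"][d.fam_idx] + sT * q["T_raw"][d.place_idx]
        mu = d.X @ gamma + sU * q["U_raw"][d.fam_idx] + sV * q["V_raw"][d.place_idx]
        sE = np.exp(q["ls_E"][0])

        pi = expit(eta)
        log1pe = np.logaddexp(0.0, eta)
        logpi, log1mpi = eta - log1pe, -log1pe
        gEta = np.zeros(d.n)
        gMu = np.zeros(d.n)
        g_lsE = 0.0
        logp = 0.0

        iz, ip, ii, il = self.idx_zero, self.idx_pos, self.idx_int, self.idx_lat
        if len(iz):
            logp += float(np.sum(log1mpi[iz]))
            gEta[iz] = -pi[iz]
        if len(ip):
            z = (self.log_d_pos - mu[ip]) / sE
            logp += float(np.sum(logpi[ip] - self.log_d_pos - np.log(sE)
                                 + _norm_logpdf(z)))
            gEta[ip] = 1.0 - pi[ip]
            gMu[ip] = z / sE
            g_lsE += float(np.sum(-1.0 + z * z))  # d/d ls = s * d/ds
        if len(ii):
            za = (d.log_lo[ii] - mu[ii]) / sE
            zb = (d.log_hi[ii] - mu[ii]) / sE
            la, lb = log_ndtr(za), log_ndtr(zb)
            logdiff = lb + np.log1p(-np.exp(np.minimum(la - lb, -1e-12)))
            logp += float(np.sum(logpi[ii] + logdiff))
            gEta[ii] = 1.0 - pi[ii]
            ga = np.exp(_norm_logpdf(za) - logdiff)
            gb = np.exp(_norm_logpdf(zb) - logdiff)
            gMu[ii] = (ga - gb) / sE
            gaza = np.zeros_like(za)  # za = -inf (with ga = 0) when d_min = 0
            fin = np.isfinite(za)
            gaza[fin] = ga[fin] * za[fin]
            g_lsE += float(np.sum(gaza - gb * zb))
        if len(il):
            zb = (d.log_hi[il] - mu[il]) / sE
            lb = log_ndtr(zb)
            ll = np.logaddexp(log1mpi[il], logpi[il] + lb)
            logp += float(np.sum(ll))
            Phi_b = np.exp(lb)
            A = np.exp(ll)
            phi_b = np.exp(_norm_logpdf(zb))
            gEta[il] = pi[il] * (1.0 - pi[il]) * (Phi_b - 1.0) / A
            gMu[il] = -pi[il] * phi_b / (sE * A)
            g_lsE += float(np.sum(-pi[il] * phi_b * zb / A))

        # chain rule into regression/intercept parameters
        g_eff = {"beta": d.X.T @ gEta, "gamma": d.X.T @ gMu}
        grad[self.slices["S_raw"]] += sS * np.bincount(d.fam_idx, gEta, self.nfam)
        grad[self.slices["T_raw"]] += sT * np.bincount(d.place_idx, gEta, self.nplace)
        grad[self.slices["U_raw"]] += sU * np.bincount(d.fam_idx, gMu, self.nfam)
        grad[self.slices["V_raw"]] += sV * np.bincount(d.place_idx, gMu, self.nplace)
        grad[self.slices["ls_S"]] += sS * float(gEta @ q["S_raw"][d.fam_idx])
        grad[self.slices["ls_T"]] += sT * float(gEta @ q["T_raw"][d.place_idx])
        grad[self.slices["ls_U"]] += sU * float(gMu @ q["U_raw"][d.fam_idx])
        grad[self.slices["ls_V"]] += sV * float(gMu @ q["V_raw"][d.place_idx])
        grad[self.slices["ls_E"]] += g_lsE

        # coefficient blocks: likelihood chain + hierarchical MVN prior
        for key, hkey, hyper, mean in (
            ("beta", "hyp_beta", self.hyper_beta, np.zeros(self.p)),
            ("gamma", "hyp_gamma", self.hyper_gamma, self.gamma_mean),
        ):
            if ncinfo is None:  # centered: sample beta directly
                grad[self.slices[key]] += g_eff[key]
                lp, gx, ghyp = hyper.mvn_with_hyperprior(q[key], mean, q[hkey])
                logp += lp
                grad[self.slices[key]] += gx
                grad[self.slices[hkey]] += ghyp
            else:  # non-centered: beta = mean + diag(tau) L raw
                tau, L, A, cache = ncinfo[key]
                raw = q[key]
                grad[self.slices[key]] += A.T @ g_eff[key]
                gA = np.outer(g_eff[key], raw)
                gtau = np.sum(gA * L, axis=1)
                gL = gA * tau[:, None]
                hp, hg = hyper.logp_grad(q[hkey], gtau, gL, cache=cache)
                logp += hp
                grad[self.slices[hkey]] += hg
                logp += -0.5 * float(raw @ raw) - 0.5 * self.p * LOG_2PI
                grad[self.slices[key]] += -raw

        # standard-normal priors on raw intercepts
        for key in ("S_raw", "T_raw", "U_raw", "V_raw"):
            x = q[key]
            logp += -0.5 * float(x @ x) - 0.5 * len(x) * LOG_2PI
            grad[self.slices[key]] += -x

        # half-Cauchy scale priors (on the log scale, Jacobian included);
        # the five log-scales are contiguous in the packing
        sl = slice(self.slices["ls_S"].start, self.slices["ls_E"].stop)
        val, g = half_cauchy_logp_grad(theta[sl])
        logp += float(np.sum(val))
        grad[sl] += g
        return logp, grad

    def logprior(self, theta):
        lp, _ = self.logp_grad(theta)
        return lp - self.loglik(theta)
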