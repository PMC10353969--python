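"""Hierarchical multi-logit model of postmarital residence.

For couple c with extended family l(c), male birthplace b_m(c) and
female birthplace b_f(c), the log-odds of residence type r (neolocal,
matrilocal, patrilocal) relative to the reference type (equilocal, the
most common type) are

    log(pi_rc / pi_ec) = x_c' delta_r + W_{r,l(c)} + Y_{r,b_m(c)} + Z_{r,b_f(c)}

The three coefficient vectors are concatenated into one delta with a
joint hierarchical MVN prior (half-Cauchy scales, LKJ(2) correlation),
allowing covariate effects to be correlated across residence types; the
family and birthplace intercept triples W, Y, Z each get their own 3x3
hierarchical covariance, and are sampled non-centered.

A ``fixed_priors`` mode replaces the hierarchical covariances with fixed
matrices; reparameterizing to a different reference category together
with the congruently transformed fixed covariances yields an
algebraically equivalent model (used by the reference-invariance tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from ._corr import LOG_2PI, HierCovPrior
from .migration import SETTLEMENT_DUMMIES, _region_dummy, ancestry_covariates

RESIDENCE_LEVELS = ("equilocal", "neolocal", "matrilocal", "patrilocal")
NONREF = RESIDENCE_LEVELS[1:]
REF_GENERATION = "grandparent"


@dataclass
class ResidenceDesign:
    X: np.ndarray
    colnames: list
    fam_idx: np.ndarray
    bm_idx: np.ndarray
    bf_idx: np.ndarray
    fam_ids: list
    place_ids: list          # shared index space for male and female birthplaces
    y: np.ndarray            # 0 equilocal .. 3 patrilocal
    ref_year: float
    variant: str
    outcomes: list = field(repr=False, default_factory=list)

    @property
    def n(self):
        return self.X.shape[0]

    @property
    def q(self):
        return self.X.shape[1]


def build_residence_design(outcomes, families, gazetteer, variant="baseline",
                           ref_year=None, ancestry_eps=1e-3,
                           birth_year_source="proband"):
    """Design for typed (non-missing) residence outcomes.

    Baseline columns: intercept, proband birth year (decades, centered at
    the sample median), generation (parent vs. grandparent), region, and
    their interaction.  The couple's place of postmarital residence is
    operationalized as the child's birthplace, which supplies both the
    region and (for the settlement variant) the settlement-size class.
    """
    rows = [o for o in outcomes if o.type != "missing"]
    if not rows:
        raise ValueError("no typed residence outcomes")
    for o in rows:
        if o.child_place is None or o.female_place is None or o.male_place is None:
            raise ValueError(f"typed outcome {o.couple_id} has unresolved birthplaces")
    fam_by_id = {f.family_id: f for f in families}
    years = {f.family_id: (float(f.proband.birth_year)
                           if f.proband.birth_year is not None else np.nan)
             for f in families}
    if ref_year is None:
        vals = np.array([y for y in years.values() if np.isfinite(y)])
        ref_year = float(np.median(vals)) if len(vals) else 0.0

    fam_ids = sorted({o.family_id for o in rows})
    place_ids = sorted({o.male_place for o in rows} | {o.female_place for o in rows})
    fmap = {f: i for i, f in enumerate(fam_ids)}
    pmap = {p: i for i, p in enumerate(place_ids)}

    gen = np.array([1.0 if o.generation != REF_GENERATION else 0.0 for o in rows])
    regions = [gazetteer[o.child_place].region for o in rows]
    _, other, reg = _region_dummy(regions, {b.region for b in gazetteer.values()})
    def _year(o):
        if birth_year_source == "child":
            fam = fam_by_id.get(o.family_id)
            child = fam.get(o.child_role) if fam else None
            if child is not None and child.birth_year is not None:
                return float(child.birth_year)
        return years.get(o.family_id, np.nan)

    byear = np.array([(_year(o) - ref_year) / 10.0 for o in rows])
    byear = np.where(np.isfinite(byear), byear, 0.0)

    cols = [np.ones(len(rows)), byear, gen, reg, gen * reg]
    rname = f"region_{other}"
    names = ["intercept", "birth_year_dec", "gen_parent", rname, f"parent_x_{rname}"]

    if variant == "settlement_size":
        for s in SETTLEMENT_DUMMIES:
            cols.append(np.array([
                1.0 if gazetteer[o.child_place].settlement_size == s else 0.0
                for o in rows]))
            names.append(f"settlement_{s}")
    elif variant == "ancestry":
        alr = {}
        for fid in fam_ids:
            fam = fam_by_id.get(fid)
            if fam is None or fam.ancestry is None:
                raise ValueError(
                    f"ancestry variant requires ancestry proportions (missing {fid!r})")
            alr[fid] = ancestry_covariates(fam.ancestry, ancestry_eps)
        cols.append(np.array([alr[o.family_id][0] for o in rows]))
        cols.append(np.array([alr[o.family_id][1] for o in rows]))
        names += ["alr_khoesan_eurasian", "alr_westafrican_eurasian"]
    elif variant != "baseline":
        raise ValueError(f"unknown variant {variant!r}")

    y = np.array([RESIDENCE_LEVELS.index(o.type) for o in rows], int)
    return ResidenceDesign(
        X=np.column_stack(cols), colnames=names,
        fam_idx=np.array([fmap[o.family_id] for o in rows], int),
        bm_idx=np.array([pmap[o.male_place] for o in rows], int),
        bf_idx=np.array([pmap[o.female_place] for o in rows], int),
        fam_ids=fam_ids, place_ids=place_ids, y=y,
        ref_year=ref_year, variant=variant, outcomes=rows,
    )


def residence_linpreds(delta, W, Y, Z, x, fam, bm, bf):
    """(eta_neolocal, eta_matrilocal, eta_patrilocal) for one couple.

    ``delta`` has shape (3, q); W, Y, Z have one length-3 row per group.
    The implicit equilocal linear predictor is 0.
    """
    return tuple(float(delta[r] @ x + W[fam, r] + Y[bm, r] + Z[bf, r]) for r in range(3))


def residence_probs(linpreds):
    """Softmax over (equilocal=0, neolocal, matrilocal, patrilocal)."""
    eta = np.concatenate([[0.0], np.asarray(linpreds, float)])
    eta = eta - np.max(eta)
    w = np.exp(eta)
    return w / w.sum()


class ResidenceModel:
    """Log-posterior (value + gradient) of the multi-logit residence model."""

    def __init__(self, design: ResidenceDesign, lkj_eta: float = 2.0,
                 fixed_priors: dict | None = None):
        self.design = design
        self.q = design.q
        self.nfam = len(design.fam_ids)
        self.nplace = len(design.place_ids)
        self.fixed = fixed_priors
        sizes = {"delta": 3 * self.q,
                 "W_raw": 3 * self.nfam, "Y_raw": 3 * self.nplace,
                 "Z_raw": 3 * self.nplace}
        if fixed_priors is None:
            self.hyper_delta = HierCovPrior(3 * self.q, lkj_eta)
            self.hyper_W = HierCovPrior(3, lkj_eta)
            self.hyper_Y = HierCovPrior(3, lkj_eta)
            self.hyper_Z = HierCovPrior(3, lkj_eta)
            sizes.update(hyp_delta=self.hyper_delta.nfree,
                         hyp_W=self.hyper_W.nfree, hyp_Y=self.hyper_Y.nfree,
                         hyp_Z=self.hyper_Z.nfree)
        else:
            self._chol_delta = np.linalg.cholesky(fixed_priors["Sigma_delta"])
            self._A = {k: np.linalg.cholesky(fixed_priors[f"Sigma_{k}"])
                       for k in ("W", "Y", "Z")}
        self.slices, ofs = {}, 0
        for k, sz in sizes.items():
            self.slices[k] = slice(ofs, ofs + sz)
            ofs += sz
        self.dim = ofs

    def unpack(self, theta):
        return {k: theta[s] for k, s in self.slices.items()}

    @property
    def param_names(self):
        names = [f"delta_{r}[{c}]" for r in NONREF for c in self.design.colnames]
        for k in ("W_raw", "Y_raw", "Z_raw"):
            n = (self.slices[k].stop - self.slices[k].start) // 3
            names += [f"{k}[{i},{r}]" for i in range(n) for r in range(3)]
        for k, s in self.slices.items():
            if k.startswith("hyp_"):
                names += [f"{k}[{i}]" for i in range(s.stop - s.start)]
        return names

    def initial_point(self, rng):
        theta = 0.01 * rng.standard_normal(self.dim)
        for k in self.slices:
            if k.startswith("hyp_"):
                K = {"hyp_delta": 3 * self.q}.get(k, 3)
                theta[self.slices[k]][:K] = -0.5 + 0.1 * rng.standard_normal(K)
        return theta

    def _transforms(self, q):
        """A matrices mapping raw normal triples to W, Y, Z rows."""
        if self.fixed is not None:
            return dict(self._A)
        out = {}
        for k, hyper in (("W", self.hyper_W), ("Y", self.hyper_Y), ("Z", self.hyper_Z)):
            tau, L = hyper.matrices(q[f"hyp_{k}"])
            out[k] = tau[:, None] * L
        return out

    def _etas(self, q, A):
        d = self.design
        delta = q["delta"].reshape(3, self.q)
        W = q["W_raw"].reshape(self.nfam, 3) @ A["W"].T
        Y = q["Y_raw"].reshape(self.nplace, 3) @ A["Y"].T
        Z = q["Z_raw"].reshape(self.nplace, 3) @ A["Z"].T
        eta = d.X @ delta.T + W[d.fam_idx] + Y[d.bm_idx] + Z[d.bf_idx]
        return eta, W, Y, Z

    def probs(self, theta):
        """(n, 4) fitted category probabilities."""
        q = self.unpack(theta)
        eta, *_ = self._etas(q, self._transforms(q))
        full = np.column_stack([np.zeros(len(eta)), eta])
        full -= logsumexp(full, axis=1, keepdims=True)
        return np.exp(full)

    def pointwise_loglik(self, theta):
        P = self.probs(theta)
        return np.log(P[np.arange(self.design.n), self.design.y])

    def loglik(self, theta):
        return float(np.sum(self.pointwise_loglik(theta)))

    def logp_grad(self, theta):
        if not np.all(np.isfinite(theta)) or np.max(np.abs(theta)) > 100.0:
            return -np.inf, np.zeros(self.dim)
        d = self.design
        q = self.unpack(theta)
        grad = np.zeros(self.dim)
        A = self._transforms(q)
        eta, W, Y, Z = self._etas(q, A)

        full = np.column_stack([np.zeros(d.n), eta])
        lse = logsumexp(full, axis=1)
        logp = float(np.sum(full[np.arange(d.n), d.y] - lse))
        P = np.exp(full - lse[:, None])
        gEta = -P[:, 1:]
        pos = d.y > 0
        gEta[np.arange(d.n)[pos], d.y[pos] - 1] += 1.0

        delta = q["delta"].reshape(3, self.q)
        grad[self.slices["delta"]] += (gEta.T @ d.X).ravel()
        gW = np.column_stack([np.bincount(d.fam_idx, gEta[:, r], self.nfam)
                              for r in range(3)])
        gY = np.column_stack([np.bincount(d.bm_idx, gEta[:, r], self.nplace)
                              for r in range(3)])
        gZ = np.column_stack([np.bincount(d.bf_idx, gEta[:, r], self.nplace)
                              for r in range(3)])

        raws = {"W": q["W_raw"].reshape(self.nfam, 3),
                "Y": q["Y_raw"].reshape(self.nplace, 3),
                "Z": q["Z_raw"].reshape(self.nplace, 3)}
        gblock = {"W": gW, "Y": gY, "Z": gZ}
        for k in ("W", "Y", "Z"):
            graw = gblock[k] @ A[k]
            grad[self.slices[f"{k}_raw"]] += graw.ravel()
            # standard-normal prior on raw triples
            x = raws[k].ravel()
            logp += -0.5 * float(x @ x) - 0.5 * len(x) * LOG_2PI
            grad[self.slices[f"{k}_raw"]] += -x
            if self.fixed is None:
                gA = gblock[k].T @ raws[k]            # (3,3)
                hyper = getattr(self, f"hyper_{k}")
                tau, L = hyper.matrices(q[f"hyp_{k}"])
                gtau = np.sum(gA * L, axis=1)
                gL = gA * tau[:, None]
                hp, hg = hyper.logp_grad(q[f"hyp_{k}"], gtau, np.tril(gL))
                logp += hp
                grad[self.slices[f"hyp_{k}"]] += hg

        # prior on concatenated delta
        if self.fixed is None:
            lp, gx, ghyp = self.hyper_delta.mvn_with_hyperprior(
                q["delta"], np.zeros(3 * self.q), q["hyp_delta"])
            logp += lp
            grad[self.slices["delta"]] += gx
            grad[self.slices["hyp_delta"]] += ghyp
        else:
            Lc = self._chol_delta
            from scipy.linalg import solve_triangular
            v = solve_triangular(Lc, q["delta"], lower=True)
            w = solve_triangular(Lc.T, v, lower=False)
            logp += (-0.5 * float(v @ v) - float(np.sum(np.log(np.diag(Lc))))
                     - 0.5 * len(v) * LOG_2PI)
            grad[self.slices["delta"]] += -w
        return logp, grad

    def logprior(self, theta):
        lp, _ = self.logp_grad(theta)
        return lp - self.loglik(theta)


def reference_shift_matrix(q: int = 1) -> np.ndarray:
    """Linear map of concatenated (neolocal, matrilocal, patrilocal) blocks
    under a switch of reference category from equilocal to neolocal.

    With equilocal reference, eta = (n, m, p); relative to neolocal the
    predictors are (-n, m-n, p-n), i.e. blocks transform by
    M = [[-1,0,0],[-1,1,0],[-1,0,1]] (Kronecker with I_q for coefficient
    vectors).  Fixed prior covariances transform as M Sigma M'.
    """
    M3 = np.array([[-1.0, 0.0, 0.0], [-1.0, 1.0, 0.0], [-1.0, 0.0, 1.0]])
    return np.kron(M3, np.eye(q)) if q > 1 else M3
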