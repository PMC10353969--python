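"""Posterior sampling, diagnostics, marginalization and model comparison.

``fit`` runs the NUTS backend over a model object exposing
``dim``, ``logp_grad`` and ``initial_point`` (the two model classes in
this package), collects per-chain draws, and computes split R-hat and
bulk/tail effective sample sizes.  ``compare_models`` ranks models by
expected log predictive density estimated with Pareto-smoothed
importance-sampling leave-one-out cross-validation (PSIS-LOO) from their
pointwise log-likelihood matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .nuts import nuts_sample

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import arviz as az


@dataclass
class FitConfig:
    chains: int = 4
    warmup: int = 6500
    draws: int = 1500
    seed: int = 0
    target_accept: float = 0.9
    init: str = "map"  # "map" (mode + jitter per chain) or "random"


@dataclass
class FitDiagnostics:
    rhat: np.ndarray
    ess_bulk: np.ndarray
    ess_tail: np.ndarray
    divergences: int
    chain_stats: list = field(default_factory=list)

    @property
    def max_rhat(self):
        return float(np.nanmax(self.rhat))


@dataclass
class PosteriorDraws:
    """Draws indexed (chain, iteration, parameter), warmup excluded."""

    names: list
    array: np.ndarray  # (chains, draws, dim)
    config: FitConfig
    diagnostics: FitDiagnostics | None = None

    @property
    def stacked(self) -> np.ndarray:
        c, d, p = self.array.shape
        return self.array.reshape(c * d, p)

    def get(self, name: str) -> np.ndarray:
        return self.stacked[:, self.names.index(name)]

    def block(self, model, key) -> np.ndarray:
        return self.stacked[:, model.slices[key]]


def _diagnostics(arr: np.ndarray, chain_stats) -> FitDiagnostics:
    darr = arr
    if darr.shape[0] == 1 and darr.shape[1] >= 4:
        # single chain: split in half so split R-hat is still defined
        half = darr.shape[1] // 2
        darr = darr[:, : 2 * half].reshape(2, half, darr.shape[2])
    ds = az.convert_to_dataset({"theta": darr})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(ds)["theta"].values
        essb = az.ess(ds, method="bulk")["theta"].values
        esst = az.ess(ds, method="tail")["theta"].values
    ndiv = int(sum(s.get("divergences", 0) for s in chain_stats))
    return FitDiagnostics(rhat=rhat, ess_bulk=essb, ess_tail=esst,
                          divergences=ndiv, chain_stats=chain_stats)


def fit(model, config: FitConfig | None = None, rhat_warn: float = 1.01,
        m_inv0=None, center0=None, eps0=None) -> PosteriorDraws:
    """Sample the model's posterior; returns draws plus diagnostics.

    Chains are seeded deterministically from ``config.seed``.  A maximum
    split R-hat above ``rhat_warn`` triggers a warning, not a failure.
    ``m_inv0``/``center0`` seed the diagonal metric and chain starting
    point (e.g. warm-started from a fit of the same model structure);
    otherwise the partial posterior mode and its curvature are used.
    """
    cfg = config or FitConfig()
    center = center0
    if cfg.init == "map" and center is None:
        center, _ = map_fit(model, np.random.default_rng([cfg.seed, 987]), maxiter=300)
        if m_inv0 is None:
            m_inv0 = _mode_curvature_metric(model, center)
    chains = []
    stats = []
    for c in range(cfg.chains):
        rng = np.random.default_rng([cfg.seed, c])
        if center is not None:
            init = center + 0.1 * rng.standard_normal(model.dim)
        else:
            init = model.initial_point(rng)
        draws, st = nuts_sample(model.logp_grad, model.dim, rng,
                                draws=cfg.draws, warmup=cfg.warmup,
                                initial=init, target_accept=cfg.target_accept,
                                m_inv0=m_inv0, eps0=eps0)
        chains.append(draws)
        stats.append(st)
    arr = np.stack(chains)
    diag = _diagnostics(arr, stats)
    if diag.max_rhat > rhat_warn:
        warnings.warn(f"max split R-hat {diag.max_rhat:.3f} exceeds {rhat_warn}",
                      RuntimeWarning)
    return PosteriorDraws(names=list(model.param_names), array=arr,
                          config=cfg, diagnostics=diag)


def _mode_curvature_metric(model, center, h=1e-3):
    """Initial inverse mass matrix from the diagonal Hessian at the mode.

    Central finite differences of the analytic gradient give the negated
    diagonal curvature; its inverse approximates the posterior variances,
    which is what the diagonal metric should be.  Clipped to a sane range
    so flat or pathological directions fall back towards unit mass.
    """
    dim = model.dim
    curv = np.empty(dim)
    e = np.zeros(dim)
    for i in range(dim):
        e[i] = h
        gp = model.logp_grad(center + e)[1][i]
        gm = model.logp_grad(center - e)[1][i]
        e[i] = 0.0
        curv[i] = -(gp - gm) / (2 * h)
    with np.errstate(divide="ignore", invalid="ignore"):
        m_inv = 1.0 / curv
    m_inv[~np.isfinite(m_inv) | (m_inv <= 0)] = 1.0
    return np.clip(m_inv, 1e-4, 1e2)


def transfer_metric(src_model, src_m_inv, dst_model):
    """Carry an adapted diagonal metric between same-structure models.

    Fixed-size blocks copy over; group-intercept blocks whose group count
    differs (families/birthplaces vary between simulated replicates) get
    the source block's mean, which is adequate because raw intercepts are
    exchangeable.
    """
    if set(src_model.slices) != set(dst_model.slices):
        return None
    out = np.ones(dst_model.dim)
    for key, dsl in dst_model.slices.items():
        ssl = src_model.slices[key]
        src = src_m_inv[ssl]
        if (ssl.stop - ssl.start) == (dsl.stop - dsl.start):
            out[dsl] = src
        else:
            out[dsl] = float(np.mean(src))
    return out


def _frozen_mask(model):
    """Coordinates held fixed during mode finding: covariance hyperparameters
    and log-scales.  The joint mode of a hierarchical model collapses into
    the funnel tip (scales -> 0, coefficients -> 0), which is a terrible
    chain initialization; freezing the scales at moderate values gives a
    ridge-like mode that locates the posterior bulk instead."""
    mask = np.zeros(model.dim, bool)
    for key, sl in model.slices.items():
        if key.startswith(("hyp_", "ls_")):
            mask[sl] = True
    return mask


def map_fit(model, rng=None, maxiter=2000, freeze_hypers=True):
    """Posterior mode via L-BFGS with the model's analytic gradient.

    With ``freeze_hypers`` (default) the covariance hyperparameters and
    scales stay at their initial values and only location parameters are
    optimized.
    """
    rng = rng or np.random.default_rng(0)
    x0 = model.initial_point(rng)
    frozen = _frozen_mask(model) if freeze_hypers else np.zeros(model.dim, bool)

    def nlp(t):
        lp, g = model.logp_grad(t)
        g = np.array(g)
        g[frozen] = 0.0
        return -lp, -g

    res = minimize(nlp, x0, jac=True, method="L-BFGS-B",
                   options=dict(maxiter=maxiter, ftol=1e-14, gtol=1e-10))
    x = np.array(res.x)
    x[frozen] = x0[frozen]
    return x, res


def summarize(draws: PosteriorDraws, names=None) -> pd.DataFrame:
    """Posterior table: moments, central intervals, diagnostics, support flag.

    ``well_supported`` marks parameters whose central 90% interval
    excludes 0.
    """
    sel = names if names is not None else draws.names
    idx = [draws.names.index(n) for n in sel]
    flat = draws.stacked[:, idx]
    qs = np.percentile(flat, [5, 25, 50, 75, 95], axis=0)
    diag = draws.diagnostics
    tab = pd.DataFrame({
        "mean": flat.mean(0), "sd": flat.std(0, ddof=1),
        "q5": qs[0], "q25": qs[1], "median": qs[2], "q75": qs[3], "q95": qs[4],
        "rhat": diag.rhat[idx] if diag is not None else np.nan,
        "ess_bulk": diag.ess_bulk[idx] if diag is not None else np.nan,
    }, index=sel)
    tab["well_supported"] = (tab["q5"] > 0) | (tab["q95"] < 0)
    return tab


# ---------------------------------------------------------------------------
# PSIS-LOO
# ---------------------------------------------------------------------------

def psis_smooth(log_ratios: np.ndarray):
    """Pareto-smooth one observation's importance log-ratios.

    The largest min(0.2*S, 3*sqrt(S)) ratios are replaced by expected
    order statistics of a generalized Pareto distribution fitted to the
    tail.  Returns ``(weights, k)`` with weights normalized to sum 1; a
    degenerate (constant) ratio vector yields uniform weights and
    ``k = -inf``.
    """
    lr = np.asarray(log_ratios, float)
    if np.ptp(lr) < 1e-12:
        return np.full(lr.shape, 1.0 / len(lr)), -np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lw, k = az.psislw(lr[None, :])
    return np.exp(lw[0]), float(np.asarray(k).ravel()[0])


@dataclass
class LooResult:
    names: list
    elpd: dict            # model -> elpd_loo
    se: dict              # model -> SE of elpd
    pointwise: dict       # model -> per-observation elpd vector
    pareto_k: dict        # model -> per-observation shape diagnostics
    diffs: pd.DataFrame   # pairwise elpd differences with SEs

    def ranking(self) -> list:
        return sorted(self.names, key=lambda m: -self.elpd[m])


def loo_elpd(pointwise_loglik: np.ndarray):
    """PSIS-LOO elpd from an (S draws, n obs) pointwise log-likelihood."""
    ll = np.asarray(pointwise_loglik, float)
    S, n = ll.shape
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lw, k = az.psislw(-ll.T)  # (n, S) normalized smoothed log-weights
    elpd_i = logsumexp(lw + ll.T, axis=1)
    return elpd_i, np.asarray(k, float).ravel()


def compare_models(pointwise: dict) -> LooResult:
    """PSIS-LOO comparison of models sharing the same observations.

    ``pointwise`` maps model name -> (draws, observations) log-likelihood
    matrix.  Pairwise elpd differences get the paired SE
    sqrt(n * var(elpd_i^A - elpd_i^B)).
    """
    names = list(pointwise)
    ns = {m: pointwise[m].shape[1] for m in names}
    if len(set(ns.values())) != 1:
        raise ValueError(f"models have mismatched observation counts: {ns}")
    n = next(iter(ns.values()))
    elpd_i, elpd, se, ks = {}, {}, {}, {}
    for m in names:
        ei, k = loo_elpd(pointwise[m])
        elpd_i[m] = ei
        elpd[m] = float(ei.sum())
        se[m] = float(np.sqrt(n * np.var(ei, ddof=1)))
        ks[m] = k
    rows = []
    for a in names:
        for b in names:
            d = elpd_i[a] - elpd_i[b]
            dse = 0.0 if a == b else float(np.sqrt(n * np.var(d, ddof=1)))
            rows.append(dict(model_a=a, model_b=b,
                             elpd_diff=float(d.sum()), se_diff=dse))
    return LooResult(names=names, elpd=elpd, se=se, pointwise=elpd_i,
                     pareto_k=ks, diffs=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# posterior marginalization over birthplace intercepts
# ---------------------------------------------------------------------------

def birthplace_cell_weights(design, gazetteer) -> dict:
    """Relative birthplace frequencies per region x generation x sex cell."""
    counts: dict = {}
    for i, o in enumerate(design.outcomes):
        region = gazetteer[o.anchor_place].region
        cell = (region, o.generation, o.sex)
        counts.setdefault(cell, {}).setdefault(o.anchor_place, 0)
        counts[cell][o.anchor_place] += 1
    weights = {}
    for cell, d in counts.items():
        tot = sum(d.values())
        weights[cell] = {p: c / tot for p, c in d.items()}
    return weights


def _cell_covariates(design, gazetteer, region, generation, sex, place_id):
    """Covariate vector for a prediction cell at the reference birth year.

    Interaction columns are named ``a_x_b[_x_c]`` over the factor tokens
    ``male``/``sex_male``, ``parent``/``gen_parent`` and ``region_<name>``,
    so each column value is the product of its factor indicators.
    """
    male = 1.0 if sex == "male" else 0.0
    parent = 1.0 if generation == "parent" else 0.0

    def factor(tok):
        if tok in ("male", "sex_male"):
            return male
        if tok in ("parent", "gen_parent"):
            return parent
        if tok.startswith("region_"):
            return 1.0 if tok == f"region_{region}" else 0.0
        raise ValueError(f"unrecognized design factor {tok!r}")

    x = np.zeros(design.p)
    for j, name in enumerate(design.colnames):
        if name == "intercept":
            x[j] = 1.0
        elif name == "birth_year_dec":
            x[j] = 0.0
        elif name.startswith("settlement_"):
            x[j] = 1.0 if gazetteer[place_id].settlement_size == name.split("_", 1)[1] else 0.0
        elif name.startswith("alr_"):
            x[j] = 0.0  # balanced-ancestry reference
        else:
            toks, prod = name.replace("region_", "REGION:"), 1.0
            for tok in toks.split("_x_"):
                prod *= factor(tok.replace("REGION:", "region_"))
            x[j] = prod
    return x


def marginalize_birthplace_effects(model, draws: PosteriorDraws, gazetteer,
                                   cells=None, weights=None) -> dict:
    """Posterior odds of migration and median distance per demographic cell.

    For every posterior draw, the cell's birthplace intercepts are mixed
    with the observed relative frequencies of birthplaces in that cell as
    weights (family intercepts are set to their central value 0); the
    covariates are evaluated at the reference birth year.  Returns
    cell -> dict(odds=draw vector, distance_km=draw vector).
    """
    design = model.design
    if weights is None:
        weights = birthplace_cell_weights(design, gazetteer)
    if cells is None:
        cells = sorted(weights)
    beta = draws.block(model, "beta")
    gamma = draws.block(model, "gamma")
    sT = np.exp(draws.block(model, "ls_T")[:, 0])
    sV = np.exp(draws.block(model, "ls_V")[:, 0])
    T = draws.block(model, "T_raw") * sT[:, None]
    V = draws.block(model, "V_raw") * sV[:, None]
    pidx = {p: i for i, p in enumerate(design.place_ids)}
    out = {}
    for cell in cells:
        region, generation, sex = cell
        w = weights.get(cell)
        if not w:
            warnings.warn(f"cell {cell} has no observed birthplaces; omitted")
            continue
        odds = np.zeros(len(beta))
        dist = np.zeros(len(beta))
        for place, wt in w.items():
            x = _cell_covariates(design, gazetteer, region, generation, sex, place)
            b = pidx[place]
            odds += wt * np.exp(beta @ x + T[:, b])
            dist += wt * np.exp(gamma @ x + V[:, b])
        out[cell] = dict(odds=odds, distance_km=dist)
    return out
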