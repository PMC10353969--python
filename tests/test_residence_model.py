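"""Multi-logit residence model: softmax algebra, likelihood, priors."""

import numpy as np
import pytest

from kinloc.inference import map_fit
from kinloc.outcomes import build_residence_outcomes
from kinloc.residence import (ResidenceModel, build_residence_design,
                              reference_shift_matrix, residence_linpreds,
                              residence_probs)
from kinloc.synthetic import SimConfig, simulate_residence_dataset

from conftest import make_family


def test_probs_symmetry_and_closed_form():
    assert np.allclose(residence_probs((0.0, 0.0, 0.0)), 0.25)
    p = residence_probs((np.log(2.0), 0.0, 0.0))
    assert np.allclose(p, [1 / 5, 2 / 5, 1 / 5, 1 / 5])


def test_probs_sum_and_shift_invariance():
    rng = np.random.default_rng(0)
    for _ in range(200):
        lp = rng.normal(0, 5, size=3)
        p = residence_probs(lp)
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(p >= 0)
    # guard against overflow for extreme predictors
    p = residence_probs((800.0, -800.0, 0.0))
    assert np.isfinite(p).all() and abs(p.sum() - 1.0) < 1e-12


def test_linpreds_construction():
    q = 3
    delta = np.zeros((3, q))
    W = np.zeros((2, 3))
    Y = np.zeros((2, 3))
    Z = np.zeros((2, 3))
    x = np.array([1.0, 0.5, -1.0])
    assert residence_linpreds(delta, W, Y, Z, x, 0, 0, 0) == (0.0, 0.0, 0.0)
    W[1, 1] = 1.0  # matrilocal family intercept only
    assert residence_linpreds(delta, W, Y, Z, x, 1, 0, 0) == (0.0, 1.0, 0.0)
    # random parameters against a naive dot-product + lookup oracle
    rng = np.random.default_rng(3)
    delta = rng.normal(size=(3, q))
    W, Y, Z = (rng.normal(size=(2, 3)) for _ in range(3))
    got = residence_linpreds(delta, W, Y, Z, x, 1, 0, 1)
    want = tuple(float(np.dot(delta[r], x) + W[1, r] + Y[0, r] + Z[1, r])
                 for r in range(3))
    assert got == pytest.approx(want)


def test_reference_shift_probabilities_identical():
    """Equilocal- and neolocal-referenced parameterizations agree exactly."""
    rng = np.random.default_rng(1)
    for _ in range(50):
        eta = rng.normal(0, 2, size=3)  # (neolocal, matrilocal, patrilocal)
        p_e = residence_probs(eta)
        M = reference_shift_matrix()
        eta_n = M @ eta  # predictors relative to neolocal
        # order with neolocal reference: (equilocal, matrilocal, patrilocal)
        scores = np.array([0.0, eta_n[0], eta_n[1], eta_n[2]])
        w = np.exp(scores - scores.max())
        p_n = w / w.sum()  # (neolocal, equilocal, matrilocal, patrilocal)
        assert np.allclose(p_e, p_n[[1, 0, 2, 3]], atol=1e-12)


@pytest.fixture(scope="module")
def res_design():
    cfg = SimConfig(seed=21, n_families={"cederberg": 20, "richtersveld": 20},
                    n_places={"cederberg": 8, "richtersveld": 8})
    fams, gaz, polys, truth = simulate_residence_dataset(cfg)
    outs = build_residence_outcomes(fams, gaz)
    return build_residence_design(outs, fams, gaz), gaz


def test_design_shape_and_indices(res_design):
    design, gaz = res_design
    assert design.q == 5
    assert design.colnames == ["intercept", "birth_year_dec", "gen_parent",
                               "region_richtersveld",
                               "parent_x_region_richtersveld"]
    # couples of one family share l(c)
    fam0 = design.outcomes[0].family_id
    idx = [i for i, o in enumerate(design.outcomes) if o.family_id == fam0]
    assert len(set(design.fam_idx[idx])) == 1


def test_settlement_variant_uses_child_birthplace(toy_gazetteer):
    gaz, _ = toy_gazetteer
    fam = make_family("f1", {"proband": "A", "mother": "B", "father": "C"},
                      birth_year=1960)
    outs = build_residence_outcomes([fam], gaz)
    design = build_residence_design(outs, [fam], gaz, variant="settlement_size")
    cols = {n: j for j, n in enumerate(design.colnames)}
    row = design.X[0]
    # child born in town A
    assert row[cols["settlement_town"]] == 1.0
    assert row[cols["settlement_farm"]] == 0.0
    assert row[cols["settlement_unknown"]] == 0.0


def test_loglik_uniform_when_zero(res_design):
    design, _ = res_design
    model = ResidenceModel(design)
    theta = np.zeros(model.dim)
    pw = model.pointwise_loglik(theta)
    assert np.allclose(pw, np.log(0.25))
    assert model.loglik(theta) == pytest.approx(design.n * np.log(0.25))
    # naive per-couple softmax oracle at a random point
    rng = np.random.default_rng(5)
    theta = model.initial_point(rng) + 0.3 * rng.standard_normal(model.dim)
    P = model.probs(theta)
    pw = model.pointwise_loglik(theta)
    for c in range(0, design.n, 7):
        assert pw[c] == pytest.approx(np.log(P[c, design.y[c]]), rel=1e-12)


def test_prior_symmetry_and_monotonicity(res_design):
    design, _ = res_design
    model = ResidenceModel(design)
    theta = np.zeros(model.dim)
    base = model.logprior(theta)
    assert np.isfinite(base)
    # growing any raw family intercept lowers the (standard normal) prior
    t2 = theta.copy()
    t2[model.slices["W_raw"]][0] = 2.0
    assert model.logprior(t2) < base
    # the three residence-type blocks enter the prior exchangeably
    t3 = theta.copy()
    t3[model.slices["delta"]][0] = 0.7            # neolocal block
    t4 = theta.copy()
    t4[model.slices["delta"]][design.q] = 0.7     # matrilocal block
    assert model.logprior(t3) == pytest.approx(model.logprior(t4))


def test_prior_draws_of_intercepts_center_on_zero(res_design, rng):
    """Monte-Carlo prior check: non-centered W rows have mean ~ 0."""
    design, _ = res_design
    model = ResidenceModel(design)
    tau = np.exp(rng.normal(0, 0.3, 3))
    from kinloc._corr import corr_chol
    L = corr_chol(rng.normal(0, 0.5, 3), 3)
    A = tau[:, None] * L
    draws = rng.standard_normal((10000, 3)) @ A.T
    assert np.abs(draws.mean(0)).max() < 4 * np.abs(A).max() / np.sqrt(10000) * 3 + 0.05


def test_map_reference_invariance(res_design):
    """MAP fitted probabilities agree under an equilocal vs neolocal reference.

    Fixed (congruently transformed) prior covariances make the two
    parameterizations exact linear reparameterizations of each other.
    """
    design, _ = res_design
    q = design.q
    Sd = np.eye(3 * q) * 2.5 ** 2
    S3 = np.eye(3) * 0.7 ** 2
    fixed_e = dict(Sigma_delta=Sd, Sigma_W=S3, Sigma_Y=S3, Sigma_Z=S3)
    model_e = ResidenceModel(design, fixed_priors=fixed_e)
    theta_e, res_e = map_fit(model_e, np.random.default_rng(0))
    P_e = model_e.probs(theta_e)

    # neolocal-referenced data and congruently transformed priors
    Mq = reference_shift_matrix(q)
    M3 = reference_shift_matrix()
    fixed_n = dict(Sigma_delta=Mq @ Sd @ Mq.T, Sigma_W=M3 @ S3 @ M3.T,
                   Sigma_Y=M3 @ S3 @ M3.T, Sigma_Z=M3 @ S3 @ M3.T)
    design_n = _reref_design(design)
    model_n = ResidenceModel(design_n, fixed_priors=fixed_n)
    theta_n, res_n = map_fit(model_n, np.random.default_rng(0))
    P_n = model_n.probs(theta_n)
    # model_n categories: (neolocal, equilocal, matrilocal, patrilocal)
    assert np.max(np.abs(P_e - P_n[:, [1, 0, 2, 3]])) < 1e-4


def _reref_design(design):
    """Same couples with neolocal as the reference category."""
    import copy
    d2 = copy.copy(design)
    remap = {0: 1, 1: 0, 2: 2, 3: 3}  # equilocal<->neolocal swap
    d2.y = np.array([remap[v] for v in design.y], int)
    return d2
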