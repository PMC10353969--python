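"""Hurdle likelihood, design construction and priors of the migration model."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import expit
from scipy.stats import lognorm

from kinloc.genealogy_io import BirthplaceRef
from kinloc.migration import (MigrationModel, ancestry_covariates,
                              build_migration_design, hurdle_logdensity)
from kinloc.outcomes import MigrationOutcome, build_migration_outcomes
from kinloc.geodesy import build_distance_matrix

from conftest import make_family


def outcome(status, d=None, interval=None, migrated="unknown"):
    return MigrationOutcome(person_id="p", family_id="f", mover_role="mother",
                            sex="female", generation="parent", anchor_place="A",
                            status=status, d=d, interval=interval,
                            migrated=migrated)


def hurdle_quadrature(lo, hi, eta, mu, sigma):
    """Oracle: integrate pi * g over [lo, hi] with adaptive quadrature."""
    pi = expit(eta)
    val, err = quad(lambda d: pi * lognorm.pdf(d, s=sigma, scale=np.exp(mu)),
                    lo, hi, limit=200)
    return val


def test_hurdle_zero_branch():
    o = outcome("observed", d=0.0, migrated="no")
    assert hurdle_logdensity(o, eta=0.0, mu=1.0, sigma_E=1.0) == pytest.approx(np.log(0.5))


def test_hurdle_positive_branch_is_weighted_lognormal():
    o = outcome("observed", d=25.0, migrated="yes")
    eta, mu, s = 0.7, np.log(20.0), 0.8
    want = np.log(expit(eta)) + lognorm.logpdf(25.0, s=s, scale=np.exp(mu))
    assert hurdle_logdensity(o, eta, mu, s) == pytest.approx(want, rel=1e-12)


def test_hurdle_interval_limits_capture_all_mass():
    o = outcome("interval_censored", interval=(1e-12, 1e12), migrated="yes")
    eta = -0.3
    got = hurdle_logdensity(o, eta, mu=np.log(20), sigma_E=1.0)
    assert got == pytest.approx(np.log(expit(eta)), abs=1e-9)


def test_hurdle_interval_matches_quadrature_oracle():
    o = outcome("interval_censored", interval=(5.0, 50.0), migrated="yes")
    got = hurdle_logdensity(o, eta=0.4, mu=np.log(20.0), sigma_E=1.0)
    want = np.log(hurdle_quadrature(5.0, 50.0, 0.4, np.log(20.0), 1.0))
    assert got == pytest.approx(want, rel=1e-8)


def test_hurdle_latent_status_limits():
    eta, mu, s = 0.3, np.log(30.0), 1.0
    near0 = outcome("status_unknown_censored", interval=(0.0, 1e-10))
    assert hurdle_logdensity(near0, eta, mu, s) == pytest.approx(
        np.log(1 - expit(eta)), abs=1e-9)
    huge = outcome("status_unknown_censored", interval=(0.0, 1e12))
    assert hurdle_logdensity(huge, eta, mu, s) == pytest.approx(0.0, abs=1e-9)


def test_assume_migrated_censoring_variant(toy_gazetteer, toy_distmatrix):
    """The config switch treats same-region censored dyads as known
    migrants on (0, d_max]; their density is pi * Phi((log d_max - mu)/s)."""
    from kinloc.genealogy_io import BirthplaceRef
    from scipy.stats import norm

    gaz, polys = toy_gazetteer
    fam = make_family("f1", {"proband": "A",
                             "mother": BirthplaceRef("region_only", "cederberg")})
    default = build_migration_outcomes([fam], toy_distmatrix, gaz, polys)
    (d0,) = [o for o in default if o.mover_role == "mother"]
    assert d0.status == "status_unknown_censored"
    variant = build_migration_outcomes([fam], toy_distmatrix, gaz, polys,
                                       same_region_assume_migrated=True)
    (v0,) = [o for o in variant if o.mover_role == "mother"]
    assert v0.status == "interval_censored"
    assert v0.interval == (0.0, d0.interval[1])
    assert v0.migrated == "yes"
    eta, mu, s = 0.4, np.log(30.0), 0.9
    want = np.log(expit(eta)) + norm.logcdf((np.log(v0.interval[1]) - mu) / s)
    assert hurdle_logdensity(v0, eta, mu, s) == pytest.approx(want, rel=1e-10)
    # model paths (numpy and compiled) handle the open-below interval
    design = build_migration_design(variant, [fam], gaz)
    model = MigrationModel(design)
    rng = np.random.default_rng(4)
    theta = model.initial_point(rng) + 0.3 * rng.standard_normal(model.dim)
    lp_f, g_f = model.logp_grad(theta)
    lp_p, g_p = model.logp_grad_py(theta)
    assert np.isfinite(lp_f) and np.all(np.isfinite(g_f))
    assert lp_f == pytest.approx(lp_p, rel=1e-10)
    assert np.allclose(g_f, g_p, rtol=1e-8, atol=1e-10)
    h = 1e-5
    for i in rng.choice(model.dim, 20, replace=False):
        e = np.zeros(model.dim)
        e[i] = h
        fd = (model.logp_grad(theta + e)[0] - model.logp_grad(theta - e)[0]) / (2 * h)
        assert abs(fd - g_f[i]) / (abs(fd) + 1e-6) < 1e-5


def test_hurdle_domain_errors():
    with pytest.raises(ValueError):
        hurdle_logdensity(outcome("observed", d=1.0, migrated="yes"), 0, 0, -1.0)
    bad = outcome("interval_censored", interval=(50.0, 50.0), migrated="yes")
    with pytest.raises(ValueError):
        hurdle_logdensity(bad, 0.0, 0.0, 1.0)


def test_hurdle_normalization_random_parameters():
    """(1 - pi) + integral of pi*g over (0, inf) == 1 for random parameters."""
    rng = np.random.default_rng(8)
    for _ in range(20):
        eta = rng.normal(0, 2)
        mu = rng.normal(np.log(50), 1)
        s = rng.uniform(0.3, 2.0)
        total = (1 - expit(eta)) + hurdle_quadrature(0, np.inf, eta, mu, s)
        assert total == pytest.approx(1.0, abs=1e-8)


def test_censoring_additivity():
    """Interval densities over (a,b) and (b,c) sum to the density over (a,c)."""
    eta, mu, s = 0.2, np.log(40), 0.9
    p = {}
    for a, b in [(5, 30), (30, 90), (5, 90)]:
        o = outcome("interval_censored", interval=(a, b), migrated="yes")
        p[(a, b)] = np.exp(hurdle_logdensity(o, eta, mu, s))
    assert p[(5, 30)] + p[(30, 90)] == pytest.approx(p[(5, 90)], rel=1e-10)


def test_model_loglik_is_sum_of_pointwise(sim_small):
    gaz, polys = sim_small["gazetteer"], sim_small["polygons"]
    outs = build_migration_outcomes(sim_small["observed"],
                                    build_distance_matrix(gaz), gaz, polys)
    design = build_migration_design(outs, sim_small["observed"], gaz)
    model = MigrationModel(design)
    theta = model.initial_point(np.random.default_rng(1))
    theta += 0.2 * np.random.default_rng(2).standard_normal(model.dim)
    pw = model.pointwise_loglik(theta)
    assert model.loglik(theta) == pytest.approx(pw.sum())
    # per-point oracle: independent hurdle_logdensity calls
    q = model.unpack(theta)
    eta, mu, _ = model._linpreds(q)
    sE = float(np.exp(q["ls_E"][0]))
    for i in (0, 3, len(pw) - 1):
        assert pw[i] == pytest.approx(
            hurdle_logdensity(design.outcomes[i], float(eta[i]), float(mu[i]), sE),
            rel=1e-10)


def test_baseline_design_columns(toy_gazetteer, toy_distmatrix):
    gaz, polys = toy_gazetteer
    fams = [make_family(f"f{i}", {"proband": "A", "mother": "B", "father": "C"},
                        birth_year=1950 + i) for i in range(5)]
    outs = build_migration_outcomes(fams, toy_distmatrix, gaz, polys)
    design = build_migration_design(outs, fams, gaz)
    assert design.p == 9
    assert design.colnames[0] == "intercept"
    assert "region_richtersveld" in design.colnames
    # two outcomes of the same family share a family index
    idx = [i for i, o in enumerate(design.outcomes) if o.family_id == "f0"]
    assert len(set(design.fam_idx[idx])) == 1
    # birth year centered at the sample median, in decades
    med = np.median([1950 + i for i in range(5)])
    i0 = design.colnames.index("birth_year_dec")
    assert design.X[idx[0], i0] == pytest.approx((1950 - med) / 10)


def test_settlement_variant_dummies(toy_gazetteer, toy_distmatrix):
    gaz, polys = toy_gazetteer
    fam = make_family("f1", {"proband": "A", "mother": "B",
                             "father": BirthplaceRef("region_only", "cederberg")})
    outs = build_migration_outcomes([fam], toy_distmatrix, gaz, polys)
    design = build_migration_design(outs, [fam], gaz, variant="settlement_size")
    assert design.p == 12
    cols = {n: j for j, n in enumerate(design.colnames)}
    by_role = {o.mover_role: i for i, o in enumerate(design.outcomes)}
    # mother born on a farm (place B)
    row = design.X[by_role["mother"]]
    assert (row[cols["settlement_farm"]], row[cols["settlement_town"]],
            row[cols["settlement_unknown"]]) == (1.0, 0.0, 0.0)
    # censored mover: settlement unknown
    row = design.X[by_role["father"]]
    assert (row[cols["settlement_farm"]], row[cols["settlement_town"]],
            row[cols["settlement_unknown"]]) == (0.0, 0.0, 1.0)


def test_ancestry_covariates_transform():
    assert ancestry_covariates((1 / 3, 1 / 3, 1 / 3)) == pytest.approx((0.0, 0.0))
    ks, wa = ancestry_covariates((0.8, 0.1, 0.1))
    assert ks == pytest.approx(np.log(8.0))
    assert wa == pytest.approx(0.0)
    ks, wa = ancestry_covariates((1.0, 0.0, 0.0), eps=1e-3)
    assert np.isfinite(ks) and np.isfinite(wa)
    with pytest.raises(ValueError):
        ancestry_covariates((-0.1, 0.6, 0.5))
    with pytest.raises(ValueError):
        ancestry_covariates((0.5, 0.2, 0.2))


def test_ancestry_variant_requires_table(toy_gazetteer, toy_distmatrix):
    gaz, polys = toy_gazetteer
    fam = make_family("f1", {"proband": "A", "mother": "B"})
    outs = build_migration_outcomes([fam], toy_distmatrix, gaz, polys)
    with pytest.raises(ValueError, match="ancestry"):
        build_migration_design(outs, [fam], gaz, variant="ancestry")
    fam2 = make_family("f2", {"proband": "A", "mother": "B"},
                       ancestry=(0.5, 0.25, 0.25))
    outs2 = build_migration_outcomes([fam2], toy_distmatrix, gaz, polys)
    design = build_migration_design(outs2, [fam2], gaz, variant="ancestry")
    assert design.p == 11


def test_logprior_shape(sim_small):
    """Prior is unimodal in the raw intercepts and respects known closed forms."""
    gaz, polys = sim_small["gazetteer"], sim_small["polygons"]
    outs = build_migration_outcomes(sim_small["observed"],
                                    build_distance_matrix(gaz), gaz, polys)
    design = build_migration_design(outs, sim_small["observed"], gaz)
    model = MigrationModel(design)
    theta = np.zeros(model.dim)
    theta[model.slices["gamma"]][0] = np.log(100.0)
    base = model.logprior(theta)
    assert np.isfinite(base)
    # shrinking any family intercept towards 0 increases the prior
    t2 = theta.copy()
    t2[model.slices["S_raw"]][0] = 1.0
    assert model.logprior(t2) < base
    # gamma intercept at log(100) is the prior mode along that axis
    t3 = theta.copy()
    t3[model.slices["gamma"]][0] = np.log(100.0) + 0.5
    assert model.logprior(t3) < base
    # half-Cauchy(0,1) at sigma=1: density 2/pi * 1/2
    from kinloc._corr import half_cauchy_logp_grad
    val, _ = half_cauchy_logp_grad(np.array([0.0]))
    assert val[0] == pytest.approx(np.log(2 / np.pi) - np.log(2))
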