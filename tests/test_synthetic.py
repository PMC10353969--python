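"""Synthetic-data generator: determinism, degradation, model consistency."""

import dataclasses

import numpy as np
import pytest
from scipy.special import expit

from kinloc.geodesy import build_distance_matrix
from kinloc.outcomes import build_migration_outcomes, build_residence_outcomes
from kinloc.synthetic import (GRANDPARENT_ROLES, SimConfig, degrade,
                              feasible_type_probs, simulate_families,
                              simulate_gazetteer, simulate_residence_dataset)


def small_cfg(**kw):
    base = dict(seed=5, n_families={"cederberg": 30, "richtersveld": 30},
                n_places={"cederberg": 10, "richtersveld": 10})
    base.update(kw)
    return SimConfig(**base)


def test_gazetteer_places_inside_their_polygons():
    cfg = small_cfg()
    gaz, polys = simulate_gazetteer(cfg)
    assert len(gaz) == 20
    for b in gaz.values():
        assert polys[b.region].contains(b.lat, b.lon)
    # the two regions do not overlap
    from shapely.geometry import Polygon
    shp = {r: Polygon([(lon, lat) for lat, lon in p.vertices])
           for r, p in polys.items()}
    assert not shp["cederberg"].intersects(shp["richtersveld"])


def test_gazetteer_deterministic_under_seed():
    a, pa = simulate_gazetteer(small_cfg())
    b, pb = simulate_gazetteer(small_cfg())
    assert list(a) == list(b)
    for k in a:
        assert (a[k].lat, a[k].lon, a[k].settlement_size) == \
            (b[k].lat, b[k].lon, b[k].settlement_size)
    assert all(pa[r].vertices == pb[r].vertices for r in pa)
    c, _ = simulate_gazetteer(small_cfg(seed=6))
    assert any(a[k].lat != c[k2].lat for k, k2 in zip(a, c))


def test_families_deterministic_and_complete():
    f1, g1, p1, t1 = simulate_families(small_cfg())
    f2, g2, p2, t2 = simulate_families(small_cfg())
    assert len(f1) == 60
    for a, b in zip(f1, f2):
        assert a.family_id == b.family_id
        for role in a.members:
            assert a.members[role].birthplace == b.members[role].birthplace
    assert t1.dyads == t2.dyads
    for fam in f1:
        assert len(fam.members) == 7
        assert all(p.birthplace.is_exact for p in fam.members.values())


def test_forced_no_migration_gives_zero_distances():
    cfg = small_cfg(beta={"intercept": -30.0}, sigma_S=0.0, sigma_T=0.0)
    fams, gaz, polys, truth = simulate_families(cfg)
    assert all(not rec["migrated"] and rec["distance"] == 0.0
               for rec in truth.dyads.values())
    outs = build_migration_outcomes(fams, build_distance_matrix(gaz), gaz, polys)
    assert all(o.status == "observed" and o.d == 0.0 for o in outs)
    res = build_residence_outcomes(fams, gaz)
    assert all(r.type == "equilocal" for r in res)


def test_forced_migration_everyone_moves():
    cfg = small_cfg(beta={"intercept": 30.0}, sigma_S=0.0, sigma_T=0.0)
    fams, gaz, polys, truth = simulate_families(cfg)
    assert all(rec["migrated"] and rec["distance"] > 0.0
               for rec in truth.dyads.values())


def test_migrant_fraction_matches_model_implied_probability():
    """Observed migrant fraction ~ the mean Bernoulli probability of the truth."""
    cfg = SimConfig(seed=12, n_families={"cederberg": 100, "richtersveld": 100},
                    n_places={"cederberg": 15, "richtersveld": 15})
    fams, gaz, polys, truth = simulate_families(cfg)
    recs = list(truth.dyads.values())
    p = np.array([expit(r["eta"]) for r in recs])
    migrated = np.array([r["migrated"] for r in recs])
    se = np.sqrt(np.sum(p * (1 - p))) / len(p)
    assert abs(migrated.mean() - p.mean()) < 3 * se + 1e-12


def test_degrade_noop_at_zero_rates():
    cfg = small_cfg(censor_rate=0.0, missing_rate=0.0)
    fams, gaz, polys, truth = simulate_families(cfg)
    obs = degrade(fams, cfg, truth, gaz)
    for a, b in zip(fams, obs):
        for role in a.members:
            assert a.members[role].birthplace == b.members[role].birthplace


def test_degrade_full_censoring_of_grandparents():
    cfg = small_cfg(censor_rate=1.0, missing_rate=0.0)
    fams, gaz, polys, truth = simulate_families(cfg)
    obs = degrade(fams, cfg, truth, gaz)
    for fam in obs:
        for role in GRANDPARENT_ROLES:
            assert fam.members[role].birthplace.kind == "region_only"
    outs = build_migration_outcomes(obs, build_distance_matrix(gaz), gaz, polys)
    gp = [o for o in outs if o.generation == "grandparent"]
    assert gp and all(o.status.endswith("censored") for o in gp)


def test_degrade_leaves_truth_and_input_untouched():
    cfg = small_cfg(censor_rate=0.5, missing_rate=0.3)
    fams, gaz, polys, truth = simulate_families(cfg)
    before = {k: dict(v) for k, v in truth.dyads.items()}
    snapshot = {(f.family_id, r): f.members[r].birthplace
                for f in fams for r in f.members}
    degrade(fams, cfg, truth, gaz)
    assert truth.dyads == before
    assert all(f.members[r].birthplace == snapshot[(f.family_id, r)]
               for f in fams for r in f.members)


def test_grandparent_missingness_depends_on_parent_migration():
    """With the dependence switch on, grandparent data are missing more often
    behind a migrant parent (odds ratio > 1 in a 2x2 tabulation)."""
    cfg = SimConfig(seed=9, n_families={"cederberg": 250, "richtersveld": 250},
                    n_places={"cederberg": 12, "richtersveld": 12},
                    censor_rate=0.0, missing_rate=0.15, grandparent_missing_or=4.0)
    fams, gaz, polys, truth = simulate_families(cfg)
    obs = degrade(fams, cfg, truth, gaz)
    from kinloc.synthetic import _PARENT_OF
    table = np.zeros((2, 2))
    for fam in obs:
        for role in GRANDPARENT_ROLES:
            parent_mig = int(truth.dyads[(fam.family_id, _PARENT_OF[role])]["migrated"])
            missing = int(fam.members[role].birthplace.kind == "unknown")
            table[parent_mig, missing] += 1
    odds_ratio = (table[1, 1] * table[0, 0]) / (table[1, 0] * table[0, 1])
    assert odds_ratio > 1.0


def test_censoring_intervals_bracket_true_distances():
    """Every censored interval contains the simulated distance (500 families)."""
    cfg = SimConfig(seed=31, n_families={"cederberg": 250, "richtersveld": 250},
                    n_places={"cederberg": 15, "richtersveld": 15},
                    censor_rate=0.5, missing_rate=0.0)
    fams, gaz, polys, truth = simulate_families(cfg)
    obs = degrade(fams, cfg, truth, gaz)
    outs = build_migration_outcomes(obs, build_distance_matrix(gaz), gaz, polys)
    censored = [o for o in outs if o.interval is not None]
    assert len(censored) > 200
    for o in censored:
        d_true = truth.dyads[(o.family_id, o.mover_role)]["distance"]
        lo, hi = o.interval
        assert lo <= d_true <= hi


def test_residence_dataset_consistency_and_determinism():
    cfg = small_cfg()
    f1, g1, p1, t1 = simulate_residence_dataset(cfg)  # internal check built in
    f2, _, _, t2 = simulate_residence_dataset(cfg)
    assert t1.couples == t2.couples
    for a, b in zip(f1, f2):
        for role in a.members:
            assert a.members[role].birthplace == b.members[role].birthplace


def test_residence_frequencies_match_feasible_softmax():
    """With full exogamy, matrilocal share follows the renormalized softmax."""
    eta_m = 2.0
    delta = {"neolocal": {"intercept": 0.0}, "matrilocal": {"intercept": eta_m},
             "patrilocal": {"intercept": 0.0}}
    cfg = SimConfig(seed=13, n_families={"cederberg": 200, "richtersveld": 200},
                    n_places={"cederberg": 12, "richtersveld": 12},
                    delta=delta, sigma_W=(0.0,) * 3, sigma_Y=(0.0,) * 3,
                    sigma_Z=(0.0,) * 3, exogamy=1.0)
    fams, gaz, polys, truth = simulate_residence_dataset(cfg)
    types = list(truth.couples.values())
    # feasible set excludes equilocality when the couple's places differ
    probs = feasible_type_probs(np.array([0.0, eta_m, 0.0]), same_place=False)
    assert probs["equilocal"] == 0.0
    expected = probs["matrilocal"]
    share = types.count("matrilocal") / len(types)
    se = np.sqrt(expected * (1 - expected) / len(types))
    assert abs(share - expected) < 4 * se


def test_truth_equilocal_whenever_feasible_when_forced():
    """Equilocality dominates wherever the couple shares a birthplace."""
    delta = {"neolocal": {"intercept": -30.0}, "matrilocal": {"intercept": -30.0},
             "patrilocal": {"intercept": -30.0}}
    cfg = small_cfg(delta=delta, sigma_W=(0.0,) * 3, sigma_Y=(0.0,) * 3,
                    sigma_Z=(0.0,) * 3, exogamy=0.0)
    fams, gaz, polys, truth = simulate_residence_dataset(cfg)
    # endogamous grandparent couples share a place, so they are all equilocal
    gp_types = [t for (fid, role), t in truth.couples.items() if role != "proband"]
    assert gp_types and all(t == "equilocal" for t in gp_types)
    # the parent couple is equilocal exactly when the parents share a birthplace
    for fam in fams:
        same = (fam.members["mother"].birthplace == fam.members["father"].birthplace)
        t = truth.couples[(fam.family_id, "proband")]
        assert (t == "equilocal") == same
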