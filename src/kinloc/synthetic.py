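"""Synthetic genealogies drawn from the two models with known parameters.

The generator emulates the structure of a two-region field study of
three-generation birthplace records: a gazetteer of towns, farms and
cities inside two disjoint regional polygons (a southern region,
"cederberg", and a more remote northern one, "richtersveld"); one
interviewed proband per family with parents and grandparents; six
child-parent migration dyads and three parent couples per family; and an
observation process that censors some birthplaces to region-only
knowledge and deletes others entirely.

Migration-driven generation walks each dyad through the true hurdle
model: a Bernoulli migration draw on the dyad's log-odds, a log-normal
distance draw for movers, and assignment of the mover's birthplace to
the gazetteer place whose distance from the anchor is closest to the
drawn distance.  Distances are thereby discretized to the place grid;
with the default gazetteer density the discretization noise is small
relative to sigma_E.  When settlement-size effects are switched on the
mover's own birthplace influences the draw, so the generator switches to
an exact discrete conditional over candidate mover places.

Residence-driven generation is type-first: couple birthplaces are formed
(with an exogamy knob), the true multi-logit supplies type
probabilities restricted to the feasible set (equilocality requires the
couple to share a birthplace), and the child's birthplace is then
assigned so the residence classifier reproduces the drawn type exactly.

All randomness flows from ``SimConfig.seed``; identical configs give
identical datasets.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit
from shapely.geometry import Point, Polygon

from .genealogy_io import Birthplace, BirthplaceRef, Family, Person, UNKNOWN_PLACE
from .geodesy import RegionPolygon, build_distance_matrix
from .outcomes import DYADS, COUPLES
from ._corr import corr_chol

REGIONS = ("cederberg", "richtersveld")
_REGION_CENTERS = {"cederberg": (-32.4, 19.0), "richtersveld": (-28.8, 17.1)}

_LOG_SQRT_2PI = 0.5 * np.log(2 * np.pi)


def _default_beta():
    # log-odds of migration; reference cell: female grandparent, cederberg
    return {
        "intercept": -0.6, "birth_year_dec": 0.15, "sex_male": 0.3,
        "gen_parent": 0.5, "region_richtersveld": 0.5,
        "male_x_parent": 0.0, "male_x_region_richtersveld": 0.0,
        "parent_x_region_richtersveld": 0.0,
        "male_x_parent_x_region_richtersveld": 0.0,
    }


def _default_gamma():
    # mean log-distance (km) among movers
    return {
        "intercept": float(np.log(45.0)), "birth_year_dec": 0.10, "sex_male": 0.4,
        "gen_parent": -0.2, "region_richtersveld": 0.5,
        "male_x_parent": 0.0, "male_x_region_richtersveld": 0.0,
        "parent_x_region_richtersveld": 0.0,
        "male_x_parent_x_region_richtersveld": 0.0,
    }


def _default_delta():
    # log-odds of each type relative to equilocal; grandparent/cederberg ref
    return {
        "neolocal": {"intercept": 0.6, "birth_year_dec": 0.15, "gen_parent": -0.8,
                     "region_richtersveld": 0.0, "parent_x_region_richtersveld": 0.0},
        "matrilocal": {"intercept": -0.4, "birth_year_dec": 0.0, "gen_parent": 0.0,
                       "region_richtersveld": 0.5, "parent_x_region_richtersveld": 0.0},
        "patrilocal": {"intercept": -0.9, "birth_year_dec": 0.0, "gen_parent": 0.0,
                       "region_richtersveld": 0.0, "parent_x_region_richtersveld": 0.0},
    }


@dataclass
class SimConfig:
    seed: int = 0
    n_families: dict = field(default_factory=lambda: {"cederberg": 150, "richtersveld": 150})
    # birthplace counts mirror the study regions (~110 and ~80 settlements)
    n_places: dict = field(default_factory=lambda: {"cederberg": 100, "richtersveld": 75})
    settlement_mix: dict = field(default_factory=lambda: {
        "city": 0.07, "town": 0.40, "farm": 0.45, "unknown": 0.08})
    median_birth_year: float = 1957.0
    birth_year_sd: float = 12.0
    # hurdle-model truth
    beta: dict = field(default_factory=_default_beta)
    gamma: dict = field(default_factory=_default_gamma)
    sigma_S: float = 0.3
    sigma_T: float = 1.0
    sigma_U: float = 0.3
    sigma_V: float = 0.5
    sigma_E: float = 1.0
    settlement_beta: dict = field(default_factory=dict)   # e.g. {"town": -1.0}
    settlement_gamma: dict = field(default_factory=dict)
    # multi-logit truth (order: neolocal, matrilocal, patrilocal)
    delta: dict = field(default_factory=_default_delta)
    sigma_W: tuple = (0.3, 0.3, 0.3)
    rho_W: float = 0.0
    sigma_Y: tuple = (0.5, 0.5, 0.5)
    sigma_Z: tuple = (0.5, 0.5, 0.5)
    exogamy: float = 0.6
    # observation process
    censor_rate: float = 0.25
    missing_rate: float = 0.12
    grandparent_missing_or: float = 1.0  # odds multiplier when the parent migrated
    # ancestry mixtures (Dirichlet mean over khoesan/west_african/eurasian)
    ancestry_mean: dict = field(default_factory=lambda: {
        "cederberg": (0.45, 0.25, 0.30), "richtersveld": (0.75, 0.08, 0.17)})
    ancestry_conc: float = 30.0

    def rng(self, *stream):
        return np.random.default_rng([int(self.seed) % (2 ** 31), *stream])


@dataclass
class TruthRecord:
    """Every latent quantity behind a simulated dataset."""

    config: SimConfig
    S: dict = field(default_factory=dict)   # family_id -> intercept
    T: dict = field(default_factory=dict)   # place_id -> intercept
    U: dict = field(default_factory=dict)
    V: dict = field(default_factory=dict)
    dyads: dict = field(default_factory=dict)  # (family_id, mover_role) -> record
    W: dict = field(default_factory=dict)   # family_id -> triple
    Y: dict = field(default_factory=dict)   # place_id -> triple
    Z: dict = field(default_factory=dict)
    couples: dict = field(default_factory=dict)  # (family_id, child_role) -> type


# ---------------------------------------------------------------------------
# gazetteer
# ---------------------------------------------------------------------------

def _region_ring(center, rng, radius_deg=0.65):
    lat0, lon0 = center
    angles = np.sort(rng.uniform(0, 2 * np.pi, 8))
    radii = radius_deg * rng.uniform(0.7, 1.0, 8)
    ring = [(lat0 + r * np.sin(a), lon0 + r * np.cos(a) / np.cos(np.radians(lat0)))
            for a, r in zip(angles, radii)]
    return tuple(ring)


def simulate_gazetteer(config: SimConfig):
    """Two disjoint convex-ish regions with birthplaces sampled inside them."""
    rng = config.rng(1)
    for attempt in range(10):
        polys = {r: RegionPolygon(r, _region_ring(_REGION_CENTERS[r], rng))
                 for r in REGIONS}
        shp = {r: Polygon([(lon, lat) for lat, lon in polys[r].vertices]) for r in REGIONS}
        if not shp["cederberg"].intersects(shp["richtersveld"]):
            break
    else:
        raise RuntimeError("could not generate disjoint region polygons")
    sizes = list(config.settlement_mix)
    probs = np.array([config.settlement_mix[s] for s in sizes], float)
    probs = probs / probs.sum()
    gaz = {}
    for r in REGIONS:
        poly = shp[r]
        minx, miny, maxx, maxy = poly.bounds
        count = 0
        while count < config.n_places[r]:
            lon = rng.uniform(minx, maxx)
            lat = rng.uniform(miny, maxy)
            if not poly.contains(Point(lon, lat)):
                continue
            pid = f"{r[:3]}_{count:03d}"
            gaz[pid] = Birthplace(pid, pid, lat, lon, r,
                                  sizes[rng.choice(len(sizes), p=probs)])
            count += 1
    return gaz, polys


# ---------------------------------------------------------------------------
# migration-driven families
# ---------------------------------------------------------------------------

def _covariates(beta: dict, sex, generation, region, byear_dec):
    male = 1.0 if sex == "male" else 0.0
    parent = 1.0 if generation == "parent" else 0.0
    rich = 1.0 if region == "richtersveld" else 0.0
    x = {"intercept": 1.0, "birth_year_dec": byear_dec, "sex_male": male,
         "gen_parent": parent, "region_richtersveld": rich,
         "male_x_parent": male * parent, "male_x_region_richtersveld": male * rich,
         "parent_x_region_richtersveld": parent * rich,
         "male_x_parent_x_region_richtersveld": male * parent * rich}
    return sum(beta.get(k, 0.0) * v for k, v in x.items())


def _draw_mover_place(anchor_pid, eta, mu, config, gaz, dmat, place_list, rng,
                      settlement_effects):
    """Mover's natal place given the anchor place and dyad-level predictors.

    Without settlement effects: Bernoulli(pi) migration, log-normal
    distance, nearest-in-distance place assignment.  With settlement
    effects (which depend on the candidate place itself): one exact
    categorical draw over {stay} + {move to p}.
    """
    bs, gs = settlement_effects
    ai = dmat.index(anchor_pid)
    if not bs and not gs:
        pi = expit(eta + 0.0)
        if rng.random() >= pi:
            return anchor_pid, False, 0.0
        d_target = float(np.exp(rng.normal(mu, config.sigma_E)))
        dists = dmat.distances[ai]
        cand = np.abs(dists - d_target)
        cand[ai] = np.inf
        j = int(np.argmin(cand))
        return place_list[j], True, float(dists[j])
    # discrete conditional including per-place settlement effects: weight
    # "stay" by 1 - pi(settlement of the natal place = anchor's) and each
    # "move to p" by pi(settlement of p) times a normalized log-normal
    # distance kernel evaluated at d(anchor, p)
    dists = dmat.distances[ai]
    s_anchor = gaz[anchor_pid].settlement_size
    kern = np.zeros(len(place_list))
    piv = np.zeros(len(place_list))
    for j, pid in enumerate(place_list):
        if j == ai:
            continue
        s = gaz[pid].settlement_size
        piv[j] = expit(eta + bs.get(s, 0.0))
        mu_j = mu + gs.get(s, 0.0)
        ld = np.log(dists[j])
        kern[j] = np.exp(-ld - np.log(config.sigma_E) - _LOG_SQRT_2PI
                         - 0.5 * ((ld - mu_j) / config.sigma_E) ** 2)
    if kern.sum() <= 0:
        return anchor_pid, False, 0.0
    kern = kern / kern.sum()
    w = piv * kern
    w[ai] = 1.0 - expit(eta + bs.get(s_anchor, 0.0))
    w = w / w.sum()
    j = int(rng.choice(len(w), p=w))
    if j == ai:
        return anchor_pid, False, 0.0
    return place_list[j], True, float(dists[j])


def simulate_families(config: SimConfig, gazetteer=None, polygons=None):
    """Three-generation families whose dyads follow the true hurdle model.

    Returns ``(families, gazetteer, polygons, truth)``; families are
    complete (no censoring/missingness) — apply :func:`degrade` for the
    observation process.
    """
    if gazetteer is None:
        gazetteer, polygons = simulate_gazetteer(config)
    dmat = build_distance_matrix(gazetteer)
    place_list = list(gazetteer)
    rng = config.rng(2)
    truth = TruthRecord(config=config)
    for pid in place_list:
        truth.T[pid] = rng.normal(0.0, config.sigma_T)
        truth.V[pid] = rng.normal(0.0, config.sigma_V)
    places_by_region = {r: [p for p in place_list if gazetteer[p].region == r]
                        for r in REGIONS}
    settlement_effects = (dict(config.settlement_beta), dict(config.settlement_gamma))

    families = []
    for region in REGIONS:
        for k in range(config.n_families[region]):
            fid = f"{region[:3]}F{k:04d}"
            S_l = rng.normal(0.0, config.sigma_S)
            U_l = rng.normal(0.0, config.sigma_U)
            truth.S[fid], truth.U[fid] = S_l, U_l
            byear = float(np.round(rng.normal(config.median_birth_year,
                                              config.birth_year_sd)))
            byear_dec = (byear - config.median_birth_year) / 10.0
            # proband's birthplace anchors the two parental dyads
            anchor = {"proband": rng.choice(places_by_region[region])}
            members = {"proband": Person(f"{fid}:proband", fid, "proband",
                                         BirthplaceRef("exact", anchor["proband"]),
                                         int(byear))}
            for child_role, mover_role in DYADS:
                a_pid = anchor[child_role]
                sex = "female" if mover_role.endswith(("mother",)) else "male"
                gen = "parent" if mover_role in ("mother", "father") else "grandparent"
                a_region = gazetteer[a_pid].region
                eta = (_covariates(config.beta, sex, gen, a_region, byear_dec)
                       + S_l + truth.T[a_pid])
                mu = (_covariates(config.gamma, sex, gen, a_region, byear_dec)
                      + U_l + truth.V[a_pid])
                pid, migrated, dist = _draw_mover_place(
                    a_pid, eta, mu, config, gazetteer, dmat, place_list, rng,
                    settlement_effects)
                members[mover_role] = Person(f"{fid}:{mover_role}", fid, mover_role,
                                             BirthplaceRef("exact", pid))
                if mover_role in ("mother", "father"):
                    anchor[mover_role] = pid
                truth.dyads[(fid, mover_role)] = dict(
                    anchor=a_pid, mover=pid, migrated=migrated, distance=dist,
                    eta=float(eta), mu=float(mu))
            anc_rng = rng
            mean = np.array(config.ancestry_mean[region])
            anc = anc_rng.dirichlet(mean * config.ancestry_conc)
            families.append(Family(fid, members, proband_sex=rng.choice(["female", "male"]),
                                   ancestry=tuple(float(a) for a in anc)))
    return families, gazetteer, polygons, truth


# ---------------------------------------------------------------------------
# observation process
# ---------------------------------------------------------------------------

GRANDPARENT_ROLES = ("maternal_grandmother", "maternal_grandfather",
                     "paternal_grandmother", "paternal_grandfather")
_PARENT_OF = {"maternal_grandmother": "mother", "maternal_grandfather": "mother",
              "paternal_grandmother": "father", "paternal_grandfather": "father"}


def degrade(families, config: SimConfig, truth: TruthRecord | None = None,
            gazetteer=None):
    """Apply censoring and missingness; the input list is left untouched.

    Grandparent birthplaces are degraded to region-only knowledge at
    ``censor_rate``; any non-proband birthplace is deleted at
    ``missing_rate``.  When ``grandparent_missing_or`` > 1 the odds of a
    grandparent's birthplace being missing are multiplied by that factor
    if the corresponding parent migrated, emulating informants knowing
    less about the forebears of parents who moved away.
    """
    rng = config.rng(3)
    out = copy.deepcopy(families)
    base_p = config.missing_rate
    for fam in out:
        for role, person in fam.members.items():
            if role == "proband" or not person.birthplace.is_exact:
                continue
            p_miss = base_p
            if role in GRANDPARENT_ROLES and config.grandparent_missing_or != 1.0:
                parent_migrated = False
                if truth is not None:
                    rec = truth.dyads.get((fam.family_id, _PARENT_OF[role]))
                    parent_migrated = bool(rec and rec["migrated"])
                if parent_migrated:
                    odds = (base_p / (1 - base_p)) * config.grandparent_missing_or
                    p_miss = odds / (1 + odds)
            if rng.random() < p_miss:
                fam.members[role] = Person(person.person_id, fam.family_id, role,
                                           UNKNOWN_PLACE, person.birth_year)
                continue
            if role in GRANDPARENT_ROLES and rng.random() < config.censor_rate:
                if gazetteer is None:
                    raise ValueError("degrade needs the gazetteer when censor_rate > 0")
                region = gazetteer[person.birthplace.ref].region
                fam.members[role] = Person(person.person_id, fam.family_id, role,
                                           BirthplaceRef("region_only", region),
                                           person.birth_year)
    return out


# ---------------------------------------------------------------------------
# residence-driven couples
# ---------------------------------------------------------------------------

def _chol3(scales, rho):
    """Cholesky-like factor of a 3x3 equicorrelated covariance; zero scales allowed."""
    s = np.asarray(scales, float)
    C = np.full((3, 3), rho) + (1 - rho) * np.eye(3)
    return s[:, None] * np.linalg.cholesky(C)


def _couple_eta(config, generation, region, byear_dec, W, Yb, Zb):
    etas = []
    for r in ("neolocal", "matrilocal", "patrilocal"):
        d = config.delta[r]
        parent = 1.0 if generation == "parent" else 0.0
        rich = 1.0 if region == "richtersveld" else 0.0
        etas.append(d.get("intercept", 0.0) + d.get("birth_year_dec", 0.0) * byear_dec
                    + d.get("gen_parent", 0.0) * parent
                    + d.get("region_richtersveld", 0.0) * rich
                    + d.get("parent_x_region_richtersveld", 0.0) * parent * rich)
    return np.array(etas) + W + Yb + Zb


def feasible_type_probs(eta3, same_place: bool) -> dict:
    """Type distribution given couple birthplaces: softmax over the feasible set.

    A couple sharing a birthplace can be equilocal or neolocal; a couple
    with distinct birthplaces can be neolocal, matrilocal or patrilocal.
    """
    scores = np.concatenate([[0.0], np.asarray(eta3, float)])
    scores -= scores.max()
    w = np.exp(scores)
    names = ("equilocal", "neolocal", "matrilocal", "patrilocal")
    feas = ("equilocal", "neolocal") if same_place else ("neolocal", "matrilocal", "patrilocal")
    mask = np.array([n in feas for n in names], float)
    w = w * mask
    w = w / w.sum()
    return dict(zip(names, w))


def simulate_residence_dataset(config: SimConfig, gazetteer=None, polygons=None):
    """Families whose three couples follow the true multi-logit model.

    Generation is type-first within the feasible set; the child's
    birthplace is then assigned so that the residence classifier
    reproduces the drawn type exactly (verified here, a failure is a
    generator bug).  Grandparent couples are drawn first so each parent's
    birthplace is consistent between the couple they belong to and the
    couple they produced.
    """
    if gazetteer is None:
        gazetteer, polygons = simulate_gazetteer(config)
    rng = config.rng(4)
    place_list = list(gazetteer)
    places_by_region = {r: [p for p in place_list if gazetteer[p].region == r]
                        for r in REGIONS}
    truth = TruthRecord(config=config)
    AW = _chol3(config.sigma_W, config.rho_W)
    for pid in place_list:
        truth.Y[pid] = np.asarray(config.sigma_Y) * rng.standard_normal(3)
        truth.Z[pid] = np.asarray(config.sigma_Z) * rng.standard_normal(3)

    families = []
    for region in REGIONS:
        for k in range(config.n_families[region]):
            fid = f"{region[:3]}R{k:04d}"
            W = AW @ rng.standard_normal(3)
            truth.W[fid] = W
            byear = float(np.round(rng.normal(config.median_birth_year,
                                              config.birth_year_sd)))
            byear_dec = (byear - config.median_birth_year) / 10.0
            members = {}
            parent_place = {}
            # grandparent couples produce the mother and the father
            for child_role, female_role, male_role in COUPLES[1:]:
                pf = rng.choice(places_by_region[region])
                if rng.random() < config.exogamy:
                    others = [p for p in places_by_region[region] if p != pf]
                    pm = rng.choice(others)
                else:
                    pm = pf
                child_pid, rtype = _draw_couple_child(
                    config, rng, "grandparent", region, byear_dec, W,
                    truth.Y[pm], truth.Z[pf], pm, pf, places_by_region[region])
                members[female_role] = Person(f"{fid}:{female_role}", fid, female_role,
                                              BirthplaceRef("exact", pf))
                members[male_role] = Person(f"{fid}:{male_role}", fid, male_role,
                                            BirthplaceRef("exact", pm))
                parent_place[child_role] = child_pid
                truth.couples[(fid, child_role)] = rtype
            pm, pf = parent_place["father"], parent_place["mother"]
            child_pid, rtype = _draw_couple_child(
                config, rng, "parent", region, byear_dec, W,
                truth.Y[pm], truth.Z[pf], pm, pf, places_by_region[region])
            members["mother"] = Person(f"{fid}:mother", fid, "mother",
                                       BirthplaceRef("exact", pf))
            members["father"] = Person(f"{fid}:father", fid, "father",
                                       BirthplaceRef("exact", pm))
            members["proband"] = Person(f"{fid}:proband", fid, "proband",
                                        BirthplaceRef("exact", child_pid), int(byear))
            truth.couples[(fid, "proband")] = rtype
            families.append(Family(fid, members))
    _verify_couple_consistency(families, truth)
    return families, gazetteer, polygons, truth


def _draw_couple_child(config, rng, generation, region, byear_dec, W, Yb, Zb,
                       male_place, female_place, region_places):
    eta = _couple_eta(config, generation, region, byear_dec, W, Yb, Zb)
    probs = feasible_type_probs(eta, male_place == female_place)
    names = list(probs)
    rtype = names[int(rng.choice(len(names), p=np.array(list(probs.values()))))]
    if rtype == "equilocal":
        child = female_place
    elif rtype == "matrilocal":
        child = female_place
    elif rtype == "patrilocal":
        child = male_place
    else:
        others = [p for p in region_places if p not in (male_place, female_place)]
        child = rng.choice(others)
    return child, rtype


def _verify_couple_consistency(families, truth):
    from .outcomes import classify_residence
    for fam in families:
        for child_role, female_role, male_role in COUPLES:
            want = truth.couples[(fam.family_id, child_role)]
            got = classify_residence(fam.members[child_role].birthplace,
                                     fam.members[female_role].birthplace,
                                     fam.members[male_role].birthplace)
            if got != want:
                raise RuntimeError(
                    f"residence generator inconsistency in {fam.family_id}/{child_role}: "
                    f"drew {want}, classifier says {got}")


# ---------------------------------------------------------------------------
# simulation-based calibration / recovery
# ---------------------------------------------------------------------------

def recovery_experiment(config: SimConfig, n_replicates: int,
                        fit_config=None, effects=None, interval=0.90):
    """Repeatedly simulate, degrade, fit, and score parameter recovery.

    For each replicate the hurdle model is fitted to a freshly simulated,
    degraded dataset; per tracked fixed effect the posterior mean, SD,
    central interval, bias and coverage indicator are recorded, along
    with the posterior mean of the birthplace scale sigma_T.  Replicates
    whose sampler run fails are recorded and excluded.
    """
    from dataclasses import replace
    import pandas as pd
    from .inference import FitConfig, fit
    from .migration import MigrationModel, build_migration_design
    from .outcomes import build_migration_outcomes

    fit_config = fit_config or FitConfig(chains=2, warmup=300, draws=300)
    if effects is None:
        effects = [k for k, v in config.beta.items() if k != "intercept" and v != 0.0]
    lo_q = 100 * (1 - interval) / 2
    hi_q = 100 - lo_q
    rows, failures = [], 0
    warm_model, warm_metric, warm_eps = None, None, None
    for rep in range(n_replicates):
        cfg = replace(config, seed=(config.seed * 1000 + rep) % (2 ** 31))
        fams, gaz, polys, truth = simulate_families(cfg)
        obs = degrade(fams, cfg, truth, gaz)
        dmat = build_distance_matrix(gaz)
        outs = build_migration_outcomes(obs, dmat, gaz, polys)
        variant = "settlement_size" if config.settlement_beta else "baseline"
        design = build_migration_design(outs, obs, gaz, variant=variant)
        model = MigrationModel(design)
        # replicates share the model structure, so the adapted metric of the
        # first replicate warm-starts the rest (with a shorter warmup)
        fc = replace(fit_config, seed=fit_config.seed * 997 + rep)
        m0 = eps0 = None
        if warm_metric is not None:
            from .inference import transfer_metric
            m0 = transfer_metric(warm_model, warm_metric, model)
            if m0 is not None:
                eps0 = warm_eps
                fc = replace(fc, warmup=max(100, fit_config.warmup // 2))
        try:
            draws = fit(model, fc, rhat_warn=np.inf, m_inv0=m0, eps0=eps0)
            if warm_metric is None:
                warm_metric = draws.diagnostics.chain_stats[0]["m_inv"]
                warm_eps = draws.diagnostics.chain_stats[0]["step_size"]
                warm_model = model
        except Exception as exc:  # noqa: BLE001 - sampler failure is data, not a crash
            failures += 1
            rows.append(dict(replicate=rep, parameter="<failed>", error=str(exc)))
            continue
        for name in effects:
            col = f"beta[{name}]"
            if col not in draws.names:
                continue
            vals = draws.get(col)
            tr = config.beta.get(name, 0.0)
            q_lo, q_hi = np.percentile(vals, [lo_q, hi_q])
            rows.append(dict(replicate=rep, parameter=col, truth=tr,
                             post_mean=float(vals.mean()), post_sd=float(vals.std(ddof=1)),
                             q_lo=float(q_lo), q_hi=float(q_hi),
                             bias=float(vals.mean() - tr),
                             covered=bool(q_lo <= tr <= q_hi)))
        st = np.exp(draws.get("ls_T"))
        rows.append(dict(replicate=rep, parameter="sigma_T", truth=config.sigma_T,
                         post_mean=float(st.mean()), post_sd=float(st.std(ddof=1)),
                         q_lo=float(np.percentile(st, lo_q)),
                         q_hi=float(np.percentile(st, hi_q)),
                         bias=float(st.mean() - config.sigma_T),
                         covered=bool(np.percentile(st, lo_q) <= config.sigma_T
                                      <= np.percentile(st, hi_q))))
    return dict(table=pd.DataFrame(rows), failures=failures)


# ---------------------------------------------------------------------------
# serialization (schemas consumed by genealogy_io)
# ---------------------------------------------------------------------------

def write_dataset(outdir, families, gazetteer, polygons, truth=None):
    """Emit genealogy.csv, gazetteer.csv, regions.geojson (+ truth.json)."""
    import pandas as pd
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    colmap = {"proband": "birthplace", "mother": "mother_birthplace",
              "father": "father_birthplace", "maternal_grandmother": "mgm_birthplace",
              "maternal_grandfather": "mgf_birthplace",
              "paternal_grandmother": "pgm_birthplace",
              "paternal_grandfather": "pgf_birthplace"}
    for fam in families:
        row = dict(family_id=fam.family_id, proband_id=fam.proband.person_id,
                   sibling_group=fam.sibling_group or "",
                   sex=fam.proband_sex or "", birth_year=fam.proband.birth_year)
        for role, col in colmap.items():
            p = fam.get(role)
            ref = p.birthplace if p else UNKNOWN_PLACE
            row[col] = ref.ref if ref.kind != "unknown" else ""
        if fam.ancestry is not None:
            row["anc_khoesan"], row["anc_west_african"], row["anc_eurasian"] = fam.ancestry
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "genealogy.csv", index=False)
    pd.DataFrame([vars(b) for b in gazetteer.values()]).to_csv(
        outdir / "gazetteer.csv", index=False)
    features = []
    for rid, poly in polygons.items():
        ring = [[lon, lat] for lat, lon in poly.vertices]
        ring.append(ring[0])
        features.append(dict(type="Feature", properties=dict(region_id=rid),
                             geometry=dict(type="Polygon", coordinates=[ring])))
    with open(outdir / "regions.geojson", "w") as fh:
        json.dump(dict(type="FeatureCollection", features=features), fh)
    if truth is not None:
        ser = dict(config=asdict(truth.config),
                   S=truth.S, T=truth.T, U=truth.U, V=truth.V,
                   dyads={f"{k[0]}|{k[1]}": v for k, v in truth.dyads.items()},
                   couples={f"{k[0]}|{k[1]}": v for k, v in truth.couples.items()})
        with open(outdir / "truth.json", "w") as fh:
            json.dump(ser, fh, default=lambda o: np.asarray(o).tolist())
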