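"""Shared fixtures: small synthetic datasets built once per session."""

import numpy as np
import pytest

from kinloc.genealogy_io import Birthplace, BirthplaceRef, Family, Person
from kinloc.geodesy import RegionPolygon, build_distance_matrix
from kinloc.synthetic import SimConfig, degrade, simulate_families


@pytest.fixture(scope="session")
def square_region():
    """1x1 degree square on the equator."""
    return RegionPolygon("square", ((0.0, 0.0), (0.0, 1.0), (1.0, 1.0), (1.0, 0.0)))


@pytest.fixture(scope="session")
def toy_gazetteer():
    """Three exact places in two regions plus matching polygons."""
    gaz = {
        "A": Birthplace("A", "Alpha", -32.2, 19.0, "cederberg", "town"),
        "B": Birthplace("B", "Bravo", -32.6, 19.3, "cederberg", "farm"),
        "C": Birthplace("C", "Charlie", -28.8, 17.0, "richtersveld", "city"),
    }
    polys = {
        "cederberg": RegionPolygon("cederberg", ((-33.0, 18.5), (-33.0, 19.8),
                                                 (-31.9, 19.8), (-31.9, 18.5))),
        "richtersveld": RegionPolygon("richtersveld", ((-29.3, 16.6), (-29.3, 17.5),
                                                       (-28.3, 17.5), (-28.3, 16.6))),
    }
    return gaz, polys


@pytest.fixture(scope="session")
def toy_distmatrix(toy_gazetteer):
    gaz, _ = toy_gazetteer
    return build_distance_matrix(gaz)


def make_family(fid, places, birth_year=1957, sibling_group=None, ancestry=None):
    """Family from a role->BirthplaceRef-or-str mapping ('A' means exact)."""
    roles = ("proband", "mother", "father", "maternal_grandmother",
             "maternal_grandfather", "paternal_grandmother", "paternal_grandfather")
    members = {}
    for role in roles:
        ref = places.get(role)
        if ref is None:
            ref = BirthplaceRef("unknown")
        elif isinstance(ref, str):
            ref = BirthplaceRef("exact", ref)
        members[role] = Person(f"{fid}:{role}", fid, role, ref,
                               birth_year if role == "proband" else None)
    return Family(fid, members, sibling_group=sibling_group, ancestry=ancestry)


@pytest.fixture(scope="session")
def sim_small():
    """A small migration-driven dataset: 2x40 families, degraded."""
    cfg = SimConfig(seed=7, n_families={"cederberg": 40, "richtersveld": 40},
                    n_places={"cederberg": 12, "richtersveld": 12})
    fams, gaz, polys, truth = simulate_families(cfg)
    obs = degrade(fams, cfg, truth, gaz)
    return dict(cfg=cfg, families=fams, observed=obs, gazetteer=gaz,
                polygons=polys, truth=truth)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231)
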