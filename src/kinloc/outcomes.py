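"""Constructing the two modeled outcomes from validated genealogies.

Migration outcomes
------------------
Each family contributes up to six child-parent dyads (proband vs. mother
and father; each parent vs. their own mother and father).  The modeled
*mover* is the parent or grandparent of the dyad; the child-side birthplace
anchors the dyad's birthplace index b(i), since it is the side that is
almost always known exactly.  A dyad is

* ``observed`` when both birthplaces are exact: the distance d is known
  and ``migrated`` is simply d > 0;
* ``status_unknown_censored`` when the mover's birthplace is known only
  as a region and that region contains the anchor's place: the distance
  lies in (0, d_max) but the migration indicator itself is latent (the
  mover may have been born exactly at the anchor place), so the hurdle
  likelihood marginalizes over it;
* ``interval_censored`` when the mover's region differs from the anchor's
  region: migration certainly occurred and d lies in (d_min, d_max), the
  nearest/farthest distances from the anchor place to the mover's region;
* ``missing`` when either endpoint is unknown (or the anchor itself is
  not exact) — such dyads carry no usable information and are excluded
  from fitting.

Residence outcomes
------------------
Each family contributes up to three parent couples (proband's parents,
mother's parents, father's parents).  A couple's postmarital residence
type compares the child's birthplace with both parents' at place_id
resolution: equilocal (same as both), matrilocal (mother only),
patrilocal (father only), neolocal (neither), or missing when any
comparison is undecidable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .genealogy_io import BirthplaceRef, Family
from .geodesy import DistanceMatrix, censoring_bounds

MIGRATION_STATUSES = ("observed", "interval_censored", "status_unknown_censored", "missing")
RESIDENCE_TYPES = ("equilocal", "neolocal", "matrilocal", "patrilocal")

#: (child role, mover role) for the six dyads of a family
DYADS = (
    ("proband", "mother"),
    ("proband", "father"),
    ("mother", "maternal_grandmother"),
    ("mother", "maternal_grandfather"),
    ("father", "paternal_grandmother"),
    ("father", "paternal_grandfather"),
)

#: (child role, female parent role, male parent role) for the three couples
COUPLES = (
    ("proband", "mother", "father"),
    ("mother", "maternal_grandmother", "maternal_grandfather"),
    ("father", "paternal_grandmother", "paternal_grandfather"),
)


@dataclass
class MigrationOutcome:
    person_id: str          # the mover
    family_id: str
    mover_role: str
    sex: str
    generation: str         # parent | grandparent (of the mover)
    anchor_place: Optional[str]  # child-side exact place_id, b(i)
    status: str
    mover_place: Optional[str] = None  # mover's exact place_id when known
    d: Optional[float] = None
    interval: Optional[tuple] = None  # (d_min, d_max) km
    migrated: str = "unknown"  # yes | no | unknown

    def __post_init__(self):
        if self.status not in MIGRATION_STATUSES:
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "observed":
            assert self.d is not None and self.d >= 0
            assert self.migrated == ("yes" if self.d > 0 else "no")
        elif self.status == "interval_censored":
            lo, hi = self.interval
            # lo == 0 arises only under the assume-migrated censoring variant
            assert 0 <= lo <= hi and self.migrated == "yes"
        elif self.status == "status_unknown_censored":
            lo, hi = self.interval
            assert lo == 0 and hi > 0 and self.migrated == "unknown"


@dataclass
class ResidenceOutcome:
    couple_id: str
    family_id: str
    child_role: str
    generation: str              # of the couple: parent | grandparent
    child_place: Optional[str]
    female_place: Optional[str]  # b_f(c)
    male_place: Optional[str]    # b_m(c)
    type: str                    # one of RESIDENCE_TYPES or "missing"


def _same_place(a: BirthplaceRef, b: BirthplaceRef, gazetteer: dict | None = None):
    """Tri-valued birthplace equality at place_id resolution.

    Returns True/False when decidable, None when not.  A region-only
    birthplace can still be decidably *different* from an exact place in
    another region (when a gazetteer is given to look regions up).
    """
    if a.kind == "unknown" or b.kind == "unknown":
        return None
    if a.is_exact and b.is_exact:
        return a.ref == b.ref
    if gazetteer is not None:
        ra = a.ref if a.kind == "region_only" else gazetteer[a.ref].region
        rb = b.ref if b.kind == "region_only" else gazetteer[b.ref].region
        if ra != rb:
            return False
    return None


def classify_residence(child: BirthplaceRef, mother: BirthplaceRef,
                       father: BirthplaceRef, gazetteer: dict | None = None) -> str:
    """Residence type from the three birthplaces of a child and its parents."""
    cm = _same_place(child, mother, gazetteer)
    cf = _same_place(child, father, gazetteer)
    if cm is None or cf is None:
        return "missing"
    if cm and cf:
        return "equilocal"
    if cm:
        return "matrilocal"
    if cf:
        return "patrilocal"
    return "neolocal"


def build_migration_outcomes(
    families: list,
    distmatrix: DistanceMatrix,
    gazetteer: dict,
    polygons: dict,
    same_region_assume_migrated: bool = False,
) -> list:
    """Six dyadic migration outcomes per family (mover = parent/grandparent).

    By default a region-only mover whose region contains the anchor place
    keeps a *latent* migration indicator (the mover may have been born at
    the anchor place itself) and the hurdle likelihood marginalizes over
    it.  With ``same_region_assume_migrated`` those dyads are instead
    treated as known migrants censored to (0, d_max].
    """
    out = []
    bounds_cache: dict = {}
    for fam in families:
        for child_role, mover_role in DYADS:
            child = fam.get(child_role)
            mover = fam.get(mover_role)
            if child is None or mover is None:
                continue
            rec = _dyad_outcome(fam, child, mover, distmatrix, gazetteer,
                                polygons, bounds_cache,
                                same_region_assume_migrated)
            out.append(rec)
    return out


def _dyad_outcome(fam, child, mover, distmatrix, gazetteer, polygons, cache,
                  same_region_assume_migrated=False):
    base = dict(
        person_id=mover.person_id,
        family_id=fam.family_id,
        mover_role=mover.role,
        sex=mover.sex,
        generation=mover.generation,
    )
    cp, mp = child.birthplace, mover.birthplace
    if not cp.is_exact or mp.kind == "unknown":
        return MigrationOutcome(anchor_place=cp.ref if cp.is_exact else None,
                                status="missing", **base)
    if mp.is_exact:
        d = distmatrix.km(cp.ref, mp.ref)
        return MigrationOutcome(anchor_place=cp.ref, status="observed", d=d,
                                migrated="yes" if d > 0 else "no",
                                mover_place=mp.ref, **base)
    # region-only mover
    region = polygons[mp.ref]
    key = (cp.ref, mp.ref)
    if key not in cache:
        place = gazetteer[cp.ref]
        cache[key] = censoring_bounds((place.lat, place.lon), region)
    d_min, d_max = cache[key]
    anchor_region = gazetteer[cp.ref].region
    if anchor_region == mp.ref or d_min == 0.0:
        # anchor lies in (or on) the mover's natal region
        if same_region_assume_migrated:
            return MigrationOutcome(anchor_place=cp.ref, status="interval_censored",
                                    interval=(0.0, d_max), migrated="yes", **base)
        return MigrationOutcome(anchor_place=cp.ref, status="status_unknown_censored",
                                interval=(0.0, d_max), migrated="unknown", **base)
    return MigrationOutcome(anchor_place=cp.ref, status="interval_censored",
                            interval=(d_min, d_max), migrated="yes", **base)


def build_residence_outcomes(families: list, gazetteer: dict | None = None) -> list:
    """Three couple-level residence outcomes per family."""
    out = []
    for fam in families:
        for child_role, female_role, male_role in COUPLES:
            child = fam.get(child_role)
            female = fam.get(female_role)
            male = fam.get(male_role)
            if child is None or female is None or male is None:
                continue
            rtype = classify_residence(child.birthplace, female.birthplace,
                                       male.birthplace, gazetteer)
            out.append(ResidenceOutcome(
                couple_id=f"{fam.family_id}:{child_role}",
                family_id=fam.family_id,
                child_role=child_role,
                generation="parent" if child_role == "proband" else "grandparent",
                child_place=child.birthplace.ref if child.birthplace.is_exact else None,
                female_place=female.birthplace.ref if female.birthplace.is_exact else None,
                male_place=male.birthplace.ref if male.birthplace.is_exact else None,
                type=rtype,
            ))
    return out


def summarize_outcomes(migration: list, residence: list, gazetteer: dict) -> dict:
    """Descriptive tables: migrant fractions, distance quartiles, residence shares."""
    mrows = []
    for m in migration:
        if m.status != "observed":
            continue
        region = gazetteer[m.anchor_place].region if m.anchor_place else None
        mrows.append(dict(region=region, generation=m.generation, sex=m.sex,
                          migrated=m.migrated == "yes", d=m.d))
    mdf = pd.DataFrame(mrows)
    if len(mdf):
        mig_tab = (
            mdf.groupby(["region", "generation", "sex"])
            .agg(n=("migrated", "size"), prop_migrated=("migrated", "mean"))
            .reset_index()
        )
        movers = mdf[mdf["migrated"]]
        if len(movers):
            dist_tab = (
                movers.groupby(["region", "generation", "sex"])["d"]
                .agg(n="size", median="median",
                     iqr=lambda s: float(np.subtract(*np.percentile(s, [75, 25]))))
                .reset_index()
            )
        else:
            dist_tab = pd.DataFrame(columns=["region", "generation", "sex", "n", "median", "iqr"])
        overall = dict(
            n_complete=int(len(mdf)),
            prop_migrated=float(mdf["migrated"].mean()),
            median_km=float(movers["d"].median()) if len(movers) else None,
            iqr_km=float(np.subtract(*np.percentile(movers["d"], [75, 25]))) if len(movers) else None,
        )
    else:
        mig_tab = pd.DataFrame(columns=["region", "generation", "sex", "n", "prop_migrated"])
        dist_tab = pd.DataFrame(columns=["region", "generation", "sex", "n", "median", "iqr"])
        overall = dict(n_complete=0, prop_migrated=None, median_km=None, iqr_km=None)

    rrows = []
    for r in residence:
        if r.type == "missing":
            continue
        region = gazetteer[r.child_place].region if r.child_place else None
        rrows.append(dict(region=region, generation=r.generation, type=r.type))
    rdf = pd.DataFrame(rrows)
    if len(rdf):
        res_tab = (
            rdf.groupby(["region", "generation", "type"]).size().rename("n").reset_index()
        )
        res_tab["share"] = res_tab["n"] / res_tab.groupby(["region", "generation"])["n"].transform("sum")
        nonequi = rdf[rdf["type"] != "equilocal"]
        shares = (nonequi["type"].value_counts(normalize=True).to_dict()
                  if len(nonequi) else {})
    else:
        res_tab = pd.DataFrame(columns=["region", "generation", "type", "n", "share"])
        shares = {}
    return dict(
        migration=mig_tab,
        distances=dist_tab,
        migration_overall=overall,
        residence=res_tab,
        residence_nonequilocal_shares=shares,
    )


def migration_to_frame(migration: list) -> pd.DataFrame:
    rows = []
    for m in migration:
        lo, hi = m.interval if m.interval else (None, None)
        rows.append(dict(person_id=m.person_id, family_id=m.family_id,
                         mover_role=m.mover_role, sex=m.sex, generation=m.generation,
                         anchor_place=m.anchor_place, status=m.status, d=m.d,
                         d_min=lo, d_max=hi, migrated=m.migrated))
    return pd.DataFrame(rows)


def residence_to_frame(residence: list) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in residence])
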