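"""Reading and validating genealogy tables, gazetteers and region polygons.

The genealogy table has one row per proband (the interviewed participant)
and carries the birthplaces of seven family members: the proband, both
parents, and all four grandparents.  A birthplace cell may name a
gazetteer place (exact knowledge), name a region (region-only knowledge,
e.g. "born somewhere in the Richtersveld"), or be empty (unknown).

The gazetteer is a CSV of places with coordinates, region membership and a
four-level settlement-size class (city / town / farm / unknown).  Region
polygons arrive as a GeoJSON FeatureCollection with one Polygon feature
per region.
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .geodesy import RegionPolygon, _check_coords

logger = logging.getLogger(__name__)

SETTLEMENT_SIZES = ("city", "town", "farm", "unknown")

ROLES = (
    "proband",
    "mother",
    "father",
    "maternal_grandmother",
    "maternal_grandfather",
    "paternal_grandmother",
    "paternal_grandfather",
)

#: role -> (sex, generation); fixed by the pedigree structure
ROLE_ATTRS = {
    "proband": (None, "proband"),
    "mother": ("female", "parent"),
    "father": ("male", "parent"),
    "maternal_grandmother": ("female", "grandparent"),
    "maternal_grandfather": ("male", "grandparent"),
    "paternal_grandmother": ("female", "grandparent"),
    "paternal_grandfather": ("male", "grandparent"),
}

_ROLE_COLUMNS = {
    "proband": "birthplace",
    "mother": "mother_birthplace",
    "father": "father_birthplace",
    "maternal_grandmother": "mgm_birthplace",
    "maternal_grandfather": "mgf_birthplace",
    "paternal_grandmother": "pgm_birthplace",
    "paternal_grandfather": "pgf_birthplace",
}


@dataclass(frozen=True)
class Birthplace:
    place_id: str
    name: str
    lat: float
    lon: float
    region: str
    settlement_size: str = "unknown"

    def __post_init__(self):
        _check_coords(self.lat, self.lon)
        if self.settlement_size not in SETTLEMENT_SIZES:
            raise ValueError(
                f"settlement_size {self.settlement_size!r} not in {SETTLEMENT_SIZES}"
            )


@dataclass(frozen=True)
class BirthplaceRef:
    """Knowledge state of one person's birthplace.

    kind is ``exact`` (ref = place_id), ``region_only`` (ref = region_id)
    or ``unknown`` (ref is None).
    """

    kind: str
    ref: Optional[str] = None

    def __post_init__(self):
        if self.kind not in ("exact", "region_only", "unknown"):
            raise ValueError(f"bad birthplace knowledge kind {self.kind!r}")
        if (self.kind == "unknown") != (self.ref is None):
            raise ValueError("ref must be None iff kind is 'unknown'")

    @property
    def is_exact(self) -> bool:
        return self.kind == "exact"


UNKNOWN_PLACE = BirthplaceRef("unknown")


@dataclass
class Person:
    person_id: str
    family_id: str
    role: str
    birthplace: BirthplaceRef = UNKNOWN_PLACE
    birth_year: Optional[int] = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def sex(self) -> Optional[str]:
        return ROLE_ATTRS[self.role][0]

    @property
    def generation(self) -> str:
        return ROLE_ATTRS[self.role][1]


@dataclass
class Family:
    """One proband plus up to six recorded forebears."""

    family_id: str
    members: dict  # role -> Person
    sibling_group: Optional[str] = None
    proband_sex: Optional[str] = None
    ancestry: Optional[tuple] = None  # (khoesan, west_african, eurasian)

    @property
    def proband(self) -> Person:
        return self.members["proband"]

    def get(self, role: str) -> Optional[Person]:
        return self.members.get(role)


class ValidationError(ValueError):
    pass


def _norm(s: str) -> str:
    return " ".join(str(s).strip().lower().split())


def read_gazetteer(path) -> dict:
    df = pd.read_csv(path, dtype={"place_id": str})
    gaz = {}
    for _, row in df.iterrows():
        pid = str(row["place_id"])
        if pid in gaz:
            raise ValidationError(f"duplicate place_id {pid!r} in gazetteer")
        gaz[pid] = Birthplace(
            place_id=pid,
            name=str(row.get("name", pid)),
            lat=float(row["lat"]),
            lon=float(row["lon"]),
            region=str(row["region"]),
            settlement_size=str(row.get("settlement_size", "unknown")),
        )
    return gaz


def read_region_polygons(path) -> dict:
    with open(path) as fh:
        gj = json.load(fh)
    polys = {}
    for feat in gj["features"]:
        rid = str(feat["properties"]["region_id"])
        coords = feat["geometry"]["coordinates"][0]  # outer ring, (lon, lat)
        polys[rid] = RegionPolygon(rid, tuple((lat, lon) for lon, lat in coords))
    return polys


def _resolve_cell(cell, gazetteer: dict, regions: dict) -> BirthplaceRef:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
        return UNKNOWN_PLACE
    token = str(cell).strip()
    if token in gazetteer:
        return BirthplaceRef("exact", token)
    # region names matched case-insensitively after whitespace normalization
    norm = _norm(token)
    for rid in regions:
        if _norm(rid) == norm:
            return BirthplaceRef("region_only", rid)
    raise ValidationError(f"birthplace {token!r} matches no gazetteer place or region")


def read_genealogy(table_path, gazetteer_path, polygons_path):
    """Read and validate a genealogy table against its gazetteer and polygons.

    Returns ``(families, gazetteer, polygons)``.  Every birthplace cell must
    resolve to a gazetteer place, a region, or be empty (unknown); anything
    else raises :class:`ValidationError` naming the offending rows.
    """
    gazetteer = read_gazetteer(gazetteer_path)
    polygons = read_region_polygons(polygons_path)
    sep = "\t" if str(table_path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(table_path, sep=sep, dtype=str)

    families, errors, seen_probands = [], [], set()
    for idx, row in df.iterrows():
        fid = str(row["family_id"])
        if fid in seen_probands:
            errors.append(f"row {idx}: duplicate proband for family {fid!r}")
            continue
        seen_probands.add(fid)
        members = {}
        for role, col in _ROLE_COLUMNS.items():
            try:
                ref = _resolve_cell(row.get(col), gazetteer, polygons)
            except ValidationError as exc:
                errors.append(f"row {idx} ({col}): {exc}")
                ref = UNKNOWN_PLACE
            by_col = "birth_year" if role == "proband" else f"{role}_birth_year"
            by = row.get(by_col)
            birth_year = int(float(by)) if by not in (None, "") and not pd.isna(by) else None
            pid = str(row["proband_id"]) if role == "proband" else f"{fid}:{role}"
            members[role] = Person(pid, fid, role, ref, birth_year)
        sib = row.get("sibling_group")
        sib = None if sib is None or pd.isna(sib) or str(sib).strip() == "" else str(sib)
        anc = None
        if {"anc_khoesan", "anc_west_african", "anc_eurasian"} <= set(df.columns):
            vals = [row.get(k) for k in ("anc_khoesan", "anc_west_african", "anc_eurasian")]
            if all(v is not None and not pd.isna(v) for v in vals):
                anc = tuple(float(v) for v in vals)
        families.append(
            Family(fid, members, sibling_group=sib,
                   proband_sex=str(row["sex"]) if "sex" in row and not pd.isna(row["sex"]) else None,
                   ancestry=anc)
        )
    if errors:
        raise ValidationError("genealogy validation failed:\n" + "\n".join(errors))
    logger.info("read %d families, %d gazetteer places, %d regions",
                len(families), len(gazetteer), len(polygons))
    return families, gazetteer, polygons


def read_ancestry_table(path) -> dict:
    """Optional per-proband ancestry proportions (three components, sum 1)."""
    df = pd.read_csv(path, dtype={"proband_id": str})
    return {
        str(r["proband_id"]): (float(r["khoesan"]), float(r["west_african"]), float(r["eurasian"]))
        for _, r in df.iterrows()
    }


def dedupe_siblings(families: list, seed: int) -> list:
    """Keep one randomly chosen proband per declared sibling group.

    Interviewing two siblings duplicates their shared parents and
    grandparents, so all but one proband per sibling group are dropped.
    Selection is a deterministic function of ``seed``.
    """
    groups: dict = {}
    singletons = []
    for fam in families:
        if fam.sibling_group is None:
            singletons.append(fam)
        else:
            groups.setdefault(fam.sibling_group, []).append(fam)
    rng = random.Random(seed)
    kept = list(singletons)
    removed = 0
    for gid in sorted(groups):
        members = sorted(groups[gid], key=lambda f: f.family_id)
        keep = rng.choice(members)
        removed += len(members) - 1
        kept.append(keep)
    if removed:
        logger.info("dedupe_siblings: removed %d of %d probands", removed, len(families))
    kept.sort(key=lambda f: f.family_id)
    return kept
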