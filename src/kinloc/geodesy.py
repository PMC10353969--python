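"""Great-circle geometry on the sphere.

Distances between birthplaces are Haversine great-circle distances.  The
sphere radius defaults to the WGS-84 equatorial radius, matching the
convention of the widely used R ``geosphere`` distance functions; it is a
module constant so analyses can substitute a mean radius if preferred.

Region polygons (used when a birthplace is known only at the regional
level) are rings of (lat, lon) vertices.  Point-to-region minimum and
maximum distances are evaluated on the polygon boundary after densifying
each edge into segments no longer than ``MAX_SEGMENT_KM``; for the small
regions involved the densification error is far below the kilometre
reporting precision of the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon

EARTH_RADIUS_KM = 6378.137
MAX_SEGMENT_KM = 1.0

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_km",
    "build_distance_matrix",
    "censoring_bounds",
    "RegionPolygon",
    "DistanceMatrix",
]


def _check_coords(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
        raise ValueError("coordinates out of range: |lat|<=90, |lon|<=180 required")


def haversine_km(a, b, radius: float = EARTH_RADIUS_KM):
    """Great-circle distance in km between coordinate pairs ``(lat, lon)``.

    Accepts scalars or broadcastable arrays of degrees.
    """
    lat1, lon1 = np.asarray(a[0], float), np.asarray(a[1], float)
    lat2, lon2 = np.asarray(b[0], float), np.asarray(b[1], float)
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    h = np.clip(h, 0.0, 1.0)
    d = 2.0 * radius * np.arcsin(np.sqrt(h))
    # exact zero for identical coordinate pairs
    same = (lat1 == lat2) & (lon1 == lon2)
    return np.where(same, 0.0, d) if d.ndim else (0.0 if same else float(d))


@dataclass(frozen=True)
class RegionPolygon:
    """A closed simple ring of (lat, lon) vertices delimiting a region."""

    region_id: str
    vertices: tuple  # ((lat, lon), ...) with >= 3 distinct vertices

    def __post_init__(self):
        verts = [tuple(map(float, v)) for v in self.vertices]
        if len(verts) >= 2 and verts[0] == verts[-1]:
            verts = verts[:-1]
        if len(verts) < 3:
            raise ValueError(f"region {self.region_id!r}: polygon needs >= 3 vertices")
        for lat, lon in verts:
            _check_coords(lat, lon)
        poly = Polygon([(lon, lat) for lat, lon in verts])
        if not poly.is_valid or poly.area == 0.0:
            raise ValueError(f"region {self.region_id!r}: ring must be simple and non-degenerate")
        object.__setattr__(self, "vertices", tuple(verts))

    def _shapely(self) -> Polygon:
        return Polygon([(lon, lat) for lat, lon in self.vertices])

    def contains(self, lat: float, lon: float) -> bool:
        poly = self._shapely()
        pt = Point(lon, lat)
        return bool(poly.contains(pt) or poly.touches(pt))

    def boundary_points(self, max_segment_km: float = MAX_SEGMENT_KM) -> np.ndarray:
        """Densified boundary as an array of (lat, lon), edges split to <= max_segment_km."""
        pts = []
        verts = self.vertices
        n = len(verts)
        for i in range(n):
            a = np.asarray(verts[i], float)
            b = np.asarray(verts[(i + 1) % n], float)
            # chord length along the edge; planar interpolation is adequate for
            # the sub-degree regions this handles
            seg_km = haversine_km(a, b)
            k = max(1, int(np.ceil(seg_km / max_segment_km)))
            for t in np.arange(k) / k:
                pts.append(a + t * (b - a))
        return np.asarray(pts, float)


def censoring_bounds(
    fixed_latlon,
    region: RegionPolygon,
    max_segment_km: float = MAX_SEGMENT_KM,
) -> tuple[float, float]:
    """Distance bounds (d_min, d_max) from a fixed point to anywhere in a region.

    d_max is the distance to the farthest location within the region
    (attained on the boundary); d_min is the distance to the nearest
    location, which is 0 when the fixed point lies inside or on the region.
    """
    lat, lon = float(fixed_latlon[0]), float(fixed_latlon[1])
    _check_coords(lat, lon)
    bpts = region.boundary_points(max_segment_km)
    d = haversine_km((lat, lon), (bpts[:, 0], bpts[:, 1]))
    d_max = float(np.max(d))
    d_min = 0.0 if region.contains(lat, lon) else float(np.min(d))
    return d_min, d_max


@dataclass
class DistanceMatrix:
    """Symmetric pairwise great-circle distance matrix over gazetteer places."""

    place_ids: list
    distances: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.distances = np.asarray(self.distances, float)
        n = len(self.place_ids)
        if self.distances.shape != (n, n):
            raise ValueError("distance matrix shape does not match place_ids")
        self._index = {p: i for i, p in enumerate(self.place_ids)}

    def km(self, a, b) -> float:
        return float(self.distances[self._index[a], self._index[b]])

    def index(self, place_id) -> int:
        return self._index[place_id]


def build_distance_matrix(gazetteer) -> DistanceMatrix:
    """Pairwise Haversine distances between all places of a gazetteer.

    ``gazetteer`` is a mapping place_id -> Birthplace (see genealogy_io).
    """
    ids = list(gazetteer)
    lat = np.array([gazetteer[p].lat for p in ids], float)
    lon = np.array([gazetteer[p].lon for p in ids], float)
    d = haversine_km((lat[:, None], lon[:, None]), (lat[None, :], lon[None, :]))
    d = np.asarray(d, float)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return DistanceMatrix(ids, d)
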