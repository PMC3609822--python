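"""Geographic indices between populations on a river landscape.

Three indices are computed per population pair: great-circle (straight)
distance between population centroids, the number of times large rivers
cross the straight line, and the *detoured* distance — the shortest
polygonal route that crosses no large river, going around headwaters
(polyline termini). Rivers are open polylines passable only beyond their
endpoints; the detour is solved on a visibility graph in a local
equirectangular projection about the pair's midpoint.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

from .errors import GeometryError, InputError

EARTH_RADIUS_KM = 6371.0
LARGE = "large"
SMALL = "small"


@dataclass
class River:
    name: str
    width_class: str                      # "large" rivers block movement
    coords: list[tuple[float, float]]     # (lon, lat) vertices, upstream last

    def __post_init__(self) -> None:
        if len(self.coords) < 2:
            raise InputError(f"river {self.name!r} needs >= 2 vertices")
        if self.width_class not in (LARGE, SMALL):
            raise InputError(f"river {self.name!r}: width_class must be "
                             f"'large' or 'small'")


@dataclass
class RiverMap:
    rivers: list[River] = field(default_factory=list)

    def large_rivers(self, width_threshold: str = LARGE) -> list[River]:
        if width_threshold == SMALL:
            return list(self.rivers)
        return [r for r in self.rivers if r.width_class == LARGE]

    @classmethod
    def from_geojson(cls, path) -> "RiverMap":
        with open(path) as fh:
            gj = json.load(fh)
        rivers = []
        for feat in gj.get("features", []):
            geom = feat.get("geometry", {})
            if geom.get("type") != "LineString":
                raise InputError("river features must be LineString geometries")
            props = feat.get("properties", {})
            rivers.append(River(
                name=props.get("name", f"river{len(rivers) + 1}"),
                width_class=props.get("width_class", LARGE),
                coords=[tuple(xy) for xy in geom["coordinates"]],
            ))
        return cls(rivers)

    def to_geojson(self, path) -> None:
        gj = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": {"type": "LineString",
                                 "coordinates": [list(xy) for xy in r.coords]},
                    "properties": {"name": r.name,
                                   "width_class": r.width_class},
                }
                for r in self.rivers
            ],
        }
        with open(path, "w") as fh:
            json.dump(gj, fh, indent=1)


def population_centroid(coords: list[tuple[float, float]]) -> tuple[float, float]:
    """Arithmetic-mean centre of gravity of (lat, lon) sample coordinates."""
    pts = [(la, lo) for la, lo in coords
           if not (math.isnan(la) or math.isnan(lo))]
    if not pts:
        raise InputError("no sample coordinates available for centroid")
    lat = sum(p[0] for p in pts) / len(pts)
    lon = sum(p[1] for p in pts) / len(pts)
    return lat, lon


def site_table(meta: pd.DataFrame) -> pd.DataFrame:
    """Population centroids from sample metadata (columns latitude/longitude)."""
    rows = {}
    for pop, grp in meta.groupby("population"):
        coords = list(zip(grp["latitude"], grp["longitude"]))
        rows[pop] = population_centroid(coords)
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=["latitude", "longitude"])
    out.index.name = "population"
    return out.sort_index()


def straight_distance(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine great-circle distance in km between (lat, lon) points."""
    la1, lo1 = map(math.radians, a)
    la2, lo2 = map(math.radians, b)
    h = math.sin((la2 - la1) / 2.0) ** 2 \
        + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(math.sqrt(h))


class _Projection:
    """Local equirectangular projection (km) about a reference latitude."""

    def __init__(self, lat0: float, lon0: float):
        self.lat0, self.lon0 = lat0, lon0
        self._kx = EARTH_RADIUS_KM * math.cos(math.radians(lat0)) * math.pi / 180
        self._ky = EARTH_RADIUS_KM * math.pi / 180

    def xy(self, lat: float, lon: float) -> tuple[float, float]:
        return ((lon - self.lon0) * self._kx, (lat - self.lat0) * self._ky)

    def river_lines(self, rivers: list[River]) -> list[LineString]:
        return [LineString([self.xy(la, lo) for lo, la in r.coords])
                for r in rivers]


def _projection_for(a, b) -> _Projection:
    return _Projection((a[0] + b[0]) / 2.0, (a[1] + b[1]) / 2.0)


def _count_crossings(seg: LineString, line: LineString) -> int:
    inter = seg.intersection(line)
    if inter.is_empty:
        return 0
    if inter.geom_type == "Point":
        return 1
    if inter.geom_type == "MultiPoint":
        return len(inter.geoms)
    # collinear overlap: a tangential run along the river counts once
    return 1


def tributary_crossings(a: tuple[float, float], b: tuple[float, float],
                        river_map: RiverMap,
                        width_threshold: str = LARGE) -> int:
    """Number of transversal crossings of segment a-b with qualifying rivers.

    Raises :class:`GeometryError` when an endpoint lies exactly on a
    qualifying river (the count is then ill-posed).
    """
    proj = _projection_for(a, b)
    pa, pb = Point(proj.xy(*a)), Point(proj.xy(*b))
    if pa.equals(pb):
        return 0
    seg = LineString([pa, pb])
    total = 0
    for line in proj.river_lines(river_map.large_rivers(width_threshold)):
        if line.distance(pa) < 1e-9 or line.distance(pb) < 1e-9:
            raise GeometryError("population centroid lies on a large river")
        total += _count_crossings(seg, line)
    return total


_OFFSET_DIRS = [(math.cos(k * math.pi / 4.0), math.sin(k * math.pi / 4.0))
                for k in range(8)]


def detoured_distance(a: tuple[float, float], b: tuple[float, float],
                      river_map: RiverMap, eps_km: float = 0.1,
                      width_threshold: str = LARGE) -> float:
    """Shortest river-avoiding route length (km) from a to b.

    The route is a polygonal path whose segments intersect no large-river
    polyline; candidate waypoints are points offset ``eps_km`` beyond every
    large-river vertex (eight compass directions), so paths can round the
    headwater terminus. Returns the straight distance when unobstructed and
    ``inf`` when no feasible route exists.
    """
    proj = _projection_for(a, b)
    pa, pb = proj.xy(*a), proj.xy(*b)
    lines = proj.river_lines(river_map.large_rivers(width_threshold))
    for line in lines:
        if line.distance(Point(pa)) < 1e-9 or line.distance(Point(pb)) < 1e-9:
            raise GeometryError("population centroid lies on a large river")

    def blocked(p, q) -> bool:
        seg = LineString([p, q])
        return any(seg.intersects(line) for line in lines)

    if not blocked(pa, pb):
        return straight_distance(a, b)

    nodes = [pa, pb]
    for line in lines:
        for vx, vy in line.coords:
            for dx, dy in _OFFSET_DIRS:
                cand = (vx + eps_km * dx, vy + eps_km * dy)
                if all(l.distance(Point(cand)) > eps_km * 0.25 for l in lines):
                    nodes.append(cand)

    g = nx.Graph()
    for i, p in enumerate(nodes):
        g.add_node(i)
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if not blocked(nodes[i], nodes[j]):
                g.add_edge(i, j, weight=math.dist(nodes[i], nodes[j]))
    try:
        length = nx.shortest_path_length(g, 0, 1, weight="weight")
    except nx.NetworkXNoPath:
        return math.inf
    # planar projection can undershoot the geodesic by a hair; a detour is
    # never shorter than the straight line
    return max(float(length), straight_distance(a, b))


def geo_index_table(sites: pd.DataFrame, river_map: RiverMap,
                    width_threshold: str = LARGE,
                    eps_km: float = 0.1) -> pd.DataFrame:
    """All three geographic indices for every unordered population pair.

    ``sites`` is indexed by population with latitude/longitude columns; the
    result has one row per pair with columns ``straight_km``, ``detoured_km``
    and ``crossings``.
    """
    pops = list(sites.index)
    if len(pops) < 2:
        raise InputError("need at least two sites")
    rows = []
    for i, pa in enumerate(pops):
        for pb in pops[i + 1:]:
            a = (float(sites.loc[pa, "latitude"]),
                 float(sites.loc[pa, "longitude"]))
            b = (float(sites.loc[pb, "latitude"]),
                 float(sites.loc[pb, "longitude"]))
            rows.append({
                "pop_a": pa,
                "pop_b": pb,
                "straight_km": straight_distance(a, b),
                "detoured_km": detoured_distance(a, b, river_map,
                                                 eps_km=eps_km,
                                                 width_threshold=width_threshold),
                "crossings": tributary_crossings(a, b, river_map,
                                                 width_threshold),
            })
    return pd.DataFrame(rows)
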