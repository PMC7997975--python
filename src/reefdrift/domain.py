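"""Coastal domains: land polygons, source/destination areas and route gates.

An :class:`Area` is a coastal polygon that both releases and receives
particles (every area is a potential source and a potential sink); areas are
collected into numbered groups, and groups inside the lagoon carry an
``interior`` flag.  A :class:`Gate` is a directed line segment across a
channel used to classify which route a trajectory took.

Domains round-trip through GeoJSON FeatureCollections: area features are
polygons with properties ``{id, group, interior}``, gate features are
LineStrings with property ``{id}``, land features are polygons tagged
``{"kind": "land"}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon, box, mapping, shape
from shapely.ops import unary_union

from .flowfield import GeoPosition


@dataclass
class Area:
    """One source/destination polygon with its group number and interior flag."""

    id: str
    group: int
    polygon: Polygon
    interior: bool = False


@dataclass
class Gate:
    """Directed channel-crossing segment used for route classification."""

    id: str
    start: GeoPosition
    end: GeoPosition
    description: str = ""

    def __post_init__(self) -> None:
        self.start = GeoPosition(*self.start)
        self.end = GeoPosition(*self.end)
        if self.start == self.end:
            raise ValueError(f"gate {self.id}: endpoints must be distinct")


@dataclass
class Domain:
    """Land polygons plus named areas (grouped) and route gates."""

    land: list[Polygon] = dc_field(default_factory=list)
    areas: list[Area] = dc_field(default_factory=list)
    gates: list[Gate] = dc_field(default_factory=list)

    # -- lookups ------------------------------------------------------------
    @property
    def groups(self) -> list[int]:
        """Sorted distinct group numbers."""
        return sorted({a.group for a in self.areas})

    @property
    def interior_groups(self) -> set[int]:
        return {a.group for a in self.areas if a.interior}

    def area_by_id(self, area_id: str) -> Area:
        for a in self.areas:
            if a.id == area_id:
                return a
        raise KeyError(f"no area with id {area_id!r}")

    def areas_in_group(self, group: int) -> list[Area]:
        return [a for a in self.areas if a.group == group]

    def gate_by_id(self, gate_id: str) -> Gate:
        for g in self.gates:
            if g.id == gate_id:
                return g
        raise KeyError(f"no gate with id {gate_id!r}")

    @property
    def land_union(self):
        return unary_union(self.land) if self.land else Polygon()

    # -- validation ---------------------------------------------------------
    def validate(self, adjacency_tol: float = 0.05,
                 bbox: tuple[float, float, float, float] | None = None) -> list[str]:
        """Check structural invariants; returns a list of violation messages.

        Areas must be pairwise non-overlapping (interiors disjoint), have
        unique ids, and each must lie on or near (within ``adjacency_tol``
        degrees of) land or the domain bounding box edge.
        """
        problems: list[str] = []
        ids = [a.id for a in self.areas]
        if len(ids) != len(set(ids)):
            problems.append("duplicate area ids")
        for i in range(len(self.areas)):
            for j in range(i + 1, len(self.areas)):
                a, b = self.areas[i], self.areas[j]
                if a.polygon.intersects(b.polygon) and not a.polygon.touches(b.polygon):
                    problems.append(f"areas {a.id} and {b.id} overlap")
        land = self.land_union
        for a in self.areas:
            near_land = (not land.is_empty) and a.polygon.distance(land) <= adjacency_tol
            near_edge = False
            if bbox is not None:
                lon0, lat0, lon1, lat1 = bbox
                px0, py0, px1, py1 = a.polygon.bounds
                near_edge = (px0 - lon0 <= adjacency_tol or lon1 - px1 <= adjacency_tol
                             or py0 - lat0 <= adjacency_tol or lat1 - py1 <= adjacency_tol)
            if not (near_land or near_edge):
                problems.append(f"area {a.id} is not adjacent to land or the domain boundary")
        return problems

    # -- rasterization helpers (used by the tracker) -------------------------
    def land_mask(self, lon: np.ndarray, lat: np.ndarray,
                  erosion: float | None = None) -> np.ndarray:
        """Water mask (1 = water) on grid nodes from the land polygons.

        A node is marked land only if it lies inside the coastline eroded by
        ``erosion`` degrees (default: half a grid cell).  Land features that
        are subgrid at the raster resolution therefore stay water in the
        hydrodynamic mask -- settlement and seeding still see the exact
        polygons -- and nodes sitting numerically on a coastline vertex are
        classified as water rather than land.
        """
        if not self.land:
            return np.ones((lat.size, lon.size), dtype=np.uint8)
        if erosion is None:
            dx = float(np.median(np.diff(lon))) if lon.size > 1 else 0.0
            dy = float(np.median(np.diff(lat))) if lat.size > 1 else 0.0
            erosion = 0.5 * min(dx, dy)
        gx, gy = np.meshgrid(lon, lat)
        land = self.land_union.buffer(-erosion) if erosion > 0 else self.land_union
        if land.is_empty:
            return np.ones((lat.size, lon.size), dtype=np.uint8)
        shapely.prepare(land)
        inside = shapely.contains_xy(land, gx.ravel(), gy.ravel())
        return (~inside).reshape(lat.size, lon.size).astype(np.uint8)

    def candidate_raster(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        """Per-node candidate-area index for fast settlement prefiltering.

        Each node is tagged with the index (into ``self.areas``) of the single
        area whose polygon intersects the node's cell box, -1 if none, or -2
        if several areas are candidates (the tracker then tests all areas).
        """
        cand = np.full((lat.size, lon.size), -1, dtype=np.int32)
        dx = float(np.median(np.diff(lon))) if lon.size > 1 else 1.0
        dy = float(np.median(np.diff(lat))) if lat.size > 1 else 1.0
        for idx, a in enumerate(self.areas):
            x0, y0, x1, y1 = a.polygon.bounds
            i0 = max(int(np.searchsorted(lon, x0 - dx)) - 1, 0)
            i1 = min(int(np.searchsorted(lon, x1 + dx)) + 1, lon.size)
            j0 = max(int(np.searchsorted(lat, y0 - dy)) - 1, 0)
            j1 = min(int(np.searchsorted(lat, y1 + dy)) + 1, lat.size)
            for j in range(j0, j1):
                for i in range(i0, i1):
                    cell = box(lon[i] - dx / 2, lat[j] - dy / 2, lon[i] + dx / 2, lat[j] + dy / 2)
                    if cell.intersects(a.polygon):
                        cand[j, i] = idx if cand[j, i] == -1 else -2
        return cand

    def packed_polygons(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Area exterior rings as packed (xs, ys, offsets) arrays for kernels."""
        xs, ys, off = [], [], [0]
        for a in self.areas:
            cx, cy = a.polygon.exterior.coords.xy
            # drop the repeated closing vertex; ray casting closes implicitly
            xs.extend(cx[:-1])
            ys.extend(cy[:-1])
            off.append(len(xs))
        return (np.asarray(xs, dtype=np.float64),
                np.asarray(ys, dtype=np.float64),
                np.asarray(off, dtype=np.int64))


# ---------------------------------------------------------------------------
# GeoJSON I/O
# ---------------------------------------------------------------------------

def write_domain(domain: Domain, path) -> None:
    """Write a domain as a GeoJSON FeatureCollection."""
    features = []
    for poly in domain.land:
        features.append({"type": "Feature", "properties": {"kind": "land"},
                         "geometry": mapping(poly)})
    for a in domain.areas:
        features.append({
            "type": "Feature",
            "properties": {"kind": "area", "id": a.id, "group": a.group, "interior": a.interior},
            "geometry": mapping(a.polygon),
        })
    for g in domain.gates:
        features.append({
            "type": "Feature",
            "properties": {"kind": "gate", "id": g.id, "description": g.description},
            "geometry": mapping(LineString([tuple(g.start), tuple(g.end)])),
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def read_domain(path) -> Domain:
    """Read a domain from a GeoJSON FeatureCollection written by write_domain."""
    with open(path) as fh:
        fc = json.load(fh)
    dom = Domain()
    for feat in fc.get("features", []):
        props = feat.get("properties") or {}
        geom = shape(feat["geometry"])
        kind = props.get("kind")
        if kind == "land":
            dom.land.append(geom)
        elif kind == "gate" or (kind is None and geom.geom_type == "LineString"):
            (x0, y0), (x1, y1) = list(geom.coords)[0], list(geom.coords)[-1]
            dom.gates.append(Gate(id=str(props["id"]), start=GeoPosition(x0, y0),
                                  end=GeoPosition(x1, y1),
                                  description=props.get("description", "")))
        else:
            dom.areas.append(Area(id=str(props["id"]), group=int(props["group"]),
                                  polygon=geom, interior=bool(props.get("interior", False))))
    return dom
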