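"""Study-area geometry: distance covariates and home-range summaries.

All geometry lives in one projected metric coordinate system (planar
Euclidean distances; the study area spans a few kilometres so curvature is
negligible).  Feature collections are exchanged as GeoJSON with a ``class``
property per feature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import (
    LineString,
    MultiPoint,
    Point,
    Polygon,
    mapping,
    shape,
)
from shapely.geometry.base import BaseGeometry

#: feature classes a covariate table requires (forest optional)
REQUIRED_CLASSES = ("village", "settlement", "road", "agriculture")


@dataclass
class Landscape:
    """Camera sites plus the named landscape feature classes."""

    sites: dict[str, tuple[float, float]]
    villages: list[BaseGeometry] = field(default_factory=list)
    settlements: list[BaseGeometry] = field(default_factory=list)
    roads: list[BaseGeometry] = field(default_factory=list)
    agriculture: list[BaseGeometry] = field(default_factory=list)
    forest_block: BaseGeometry | None = None
    abandoned_villages: list[BaseGeometry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("site ids must be unique")

    def site_points(self) -> dict[str, Point]:
        return {sid: Point(x, y) for sid, (x, y) in self.sites.items()}

    def site_coords(self) -> np.ndarray:
        """(n_sites, 2) coordinate array in site-id order."""
        return np.array([self.sites[s] for s in self.sites], dtype=float)


def nearest_distance(point: Point | tuple, features: Sequence[BaseGeometry]) -> float:
    """Euclidean distance from a point to the nearest feature.

    Points on or inside a polygon are *at* the feature: distance 0.
    """
    if len(features) == 0:
        raise ValueError("empty feature set")
    p = Point(point) if not isinstance(point, Point) else point
    return float(min(p.distance(f) for f in features))


def covariate_table(landscape: Landscape) -> pd.DataFrame:
    """Per-site distance covariates (metres).

    dist_village pools villages and settlements (both are occupied human
    clusters; the covariate is one risk gradient).  dist_forest is included
    only when a forest block polygon is present.
    """
    missing = []
    if not (landscape.villages or landscape.settlements):
        missing.append("village/settlement")
    if not landscape.roads:
        missing.append("road")
    if not landscape.agriculture:
        missing.append("agriculture")
    if missing:
        raise ValueError(f"missing landscape feature class(es): {', '.join(missing)}")

    village_like = list(landscape.villages) + list(landscape.settlements)
    rows = {}
    for sid, pt in landscape.site_points().items():
        row = {
            "dist_village": nearest_distance(pt, village_like),
            "dist_road": nearest_distance(pt, landscape.roads),
            "dist_agriculture": nearest_distance(pt, landscape.agriculture),
        }
        if landscape.forest_block is not None:
            row["dist_forest"] = nearest_distance(pt, [landscape.forest_block])
        rows[sid] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "site_id"
    return out


def mcp_home_range(
    points: Sequence[tuple[float, float]], percent: float = 100.0
) -> tuple[Polygon, float]:
    """Minimum convex polygon home range and its area in km^2.

    ``percent`` < 100 drops the points farthest from the centroid (arithmetic
    mean of the coordinates) before hulling, keeping the stated fraction.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 points for a home-range polygon")
    if not (0 < percent <= 100):
        raise ValueError("percent must be in (0, 100]")
    if percent < 100:
        centroid = pts.mean(axis=0)
        d = np.linalg.norm(pts - centroid, axis=1)
        keep = max(3, int(np.ceil(pts.shape[0] * percent / 100.0)))
        pts = pts[np.argsort(d)[:keep]]
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if not isinstance(hull, Polygon):
        raise ValueError("points are collinear; home-range polygon undefined")
    return hull, hull.area / 1e6


# ---------------------------------------------------------------------------
# GeoJSON I/O


def landscape_to_geojson(landscape: Landscape) -> dict:
    """Serialise to a FeatureCollection with a `class` property per feature."""
    feats = []

    def add(geom: BaseGeometry, cls: str, **props) -> None:
        feats.append(
            {"type": "Feature", "geometry": mapping(geom), "properties": {"class": cls, **props}}
        )

    for sid, (x, y) in landscape.sites.items():
        add(Point(x, y), "site", site_id=sid)
    for g in landscape.villages:
        add(g, "village")
    for g in landscape.settlements:
        add(g, "settlement")
    for g in landscape.roads:
        add(g, "road")
    for g in landscape.agriculture:
        add(g, "agriculture")
    if landscape.forest_block is not None:
        add(landscape.forest_block, "forest_block")
    for g in landscape.abandoned_villages:
        add(g, "abandoned_village")
    return {"type": "FeatureCollection", "features": feats}


def landscape_from_geojson(doc: dict | str) -> Landscape:
    """Parse a FeatureCollection produced by :func:`landscape_to_geojson`."""
    if isinstance(doc, str):
        doc = json.loads(doc)
    sites: dict[str, tuple[float, float]] = {}
    buckets: dict[str, list[BaseGeometry]] = {
        "village": [], "settlement": [], "road": [], "agriculture": [],
        "abandoned_village": [],
    }
    forest = None
    for feat in doc["features"]:
        cls = feat.get("properties", {}).get("class")
        geom = shape(feat["geometry"])
        if cls == "site":
            sid = str(feat["properties"]["site_id"])
            sites[sid] = (geom.x, geom.y)
        elif cls == "forest_block":
            forest = geom
        elif cls in buckets:
            buckets[cls].append(geom)
    return Landscape(
        sites=sites,
        villages=buckets["village"],
        settlements=buckets["settlement"],
        roads=buckets["road"],
        agriculture=buckets["agriculture"],
        forest_block=forest,
        abandoned_villages=buckets["abandoned_village"],
    )
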