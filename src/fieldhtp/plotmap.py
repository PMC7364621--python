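"""Plot-boundary maps and spatial clipping of observations.

Experimental plot boundaries arrive as GeoJSON polygon features in UTM
coordinates (the CRS property carries the EPSG code, e.g. EPSG:32612
for zone 12 N).  Each georeferenced observation is assigned to the plot
whose polygon contains its *sensor* position -- the sensor, not the
vehicle, reflects the field of view.  Boundary points count as inside
(deterministic tie-break); coordinates are treated as planar within one
zone.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, shape
from shapely.strtree import STRtree


class PlotMapError(ValueError):
    """Invalid plot-map file or zone mismatch."""


@dataclass
class PlotPolygon:
    plot_id: str
    polygon: Polygon
    attributes: dict = field(default_factory=dict)


@dataclass
class PlotMap:
    plots: list[PlotPolygon]
    zone: int
    hemisphere: str = "N"

    def __len__(self) -> int:
        return len(self.plots)

    def __iter__(self):
        return iter(self.plots)

    def polygon(self, plot_id: str) -> PlotPolygon:
        for p in self.plots:
            if p.plot_id == plot_id:
                return p
        raise KeyError(plot_id)

    @property
    def plot_ids(self) -> list[str]:
        return [p.plot_id for p in self.plots]

    def attribute_table(self) -> pd.DataFrame:
        rows = [{"plot_id": p.plot_id, **p.attributes} for p in self.plots]
        return pd.DataFrame(rows)


def _epsg_to_zone(epsg: int) -> tuple[int, str]:
    if 32601 <= epsg <= 32660:
        return epsg - 32600, "N"
    if 32701 <= epsg <= 32760:
        return epsg - 32700, "S"
    raise PlotMapError(f"EPSG:{epsg} is not a UTM/WGS84 code")


def load_plot_map(path) -> PlotMap:
    """Load and validate a GeoJSON plot map.

    Requirements: polygon features only, a ``plot_id`` property on each
    feature, unique plot ids, simple positive-area rings, one UTM zone
    (from the collection-level ``crs`` name).  Overlap between distinct
    plots is validated and warned about, not fatal.
    """
    path = Path(path)
    doc = json.loads(path.read_text())
    if doc.get("type") != "FeatureCollection":
        raise PlotMapError(f"{path} is not a GeoJSON FeatureCollection")
    crs_name = doc.get("crs", {}).get("properties", {}).get("name", "")
    m = re.search(r"EPSG:+(\d+)", str(crs_name))
    if not m:
        raise PlotMapError(f"{path} lacks an EPSG-coded CRS property")
    zone, hemisphere = _epsg_to_zone(int(m.group(1)))

    plots: list[PlotPolygon] = []
    seen: set[str] = set()
    for i, feat in enumerate(doc.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise PlotMapError(
                f"feature {i}: non-polygon geometry {geom.get('type')!r}")
        props = dict(feat.get("properties") or {})
        if "plot_id" not in props:
            raise PlotMapError(f"feature {i}: missing plot_id attribute")
        pid = str(props.pop("plot_id"))
        if pid in seen:
            raise PlotMapError(f"duplicate plot_id {pid!r}")
        seen.add(pid)
        poly = shape(geom)
        if not poly.is_valid or poly.area <= 0:
            raise PlotMapError(f"plot {pid!r}: ring is not simple or has zero area")
        plots.append(PlotPolygon(pid, poly, props))

    if not plots:
        warnings.warn(f"{path}: empty feature collection", stacklevel=2)
    else:
        union_area = shapely.unary_union([p.polygon for p in plots]).area
        total = sum(p.polygon.area for p in plots)
        if total - union_area > 1e-6 * max(total, 1.0):
            warnings.warn("plot polygons overlap with nonzero area", stacklevel=2)
    return PlotMap(plots, zone, hemisphere)


def clip_observations(observations: pd.DataFrame, plot_map: PlotMap,
                      x_col: str = "sensor_e", y_col: str = "sensor_n",
                      zone_col: str = "utm_zone") -> pd.DataFrame:
    """Assign each observation to at most one plot.

    Adds/overwrites a ``plot_id`` column; observations inside no polygon
    get ``None`` (they are excluded from clipped exports downstream).
    Containment includes polygon boundaries.  If the observations carry
    a UTM-zone column it must match the map's zone (fatal otherwise).
    With overlapping plots the lexicographically smallest plot_id wins.
    """
    out = observations.copy()
    if zone_col in out.columns and len(out):
        zones = pd.unique(out[zone_col].dropna())
        if len(zones) and set(int(z) for z in zones) != {plot_map.zone}:
            raise PlotMapError(
                f"zone mismatch: observations in {sorted(zones)}, map in {plot_map.zone}")
    out["plot_id"] = None
    if not len(out) or not len(plot_map.plots):
        return out
    order = np.argsort(np.array([p.plot_id for p in plot_map.plots]))
    polys = [plot_map.plots[i] for i in order]
    tree = STRtree([p.polygon for p in polys])
    xy = out[[x_col, y_col]].to_numpy(dtype=float)
    valid = np.isfinite(xy).all(axis=1)
    pts = shapely.points(xy[valid])
    pt_idx, poly_idx = tree.query(pts, predicate="intersects")
    # smallest plot_id (earliest in sorted order) wins any overlap tie
    assigned = np.full(len(pts), len(polys), dtype=int)
    np.minimum.at(assigned, pt_idx, poly_idx)
    ids = np.array([p.plot_id for p in polys] + [None], dtype=object)
    col = np.full(len(out), None, dtype=object)
    col[np.flatnonzero(valid)] = ids[assigned]
    out["plot_id"] = col
    return out


def _centerline_axes(poly: Polygon):
    """Long-axis unit vector and centroid of a (near-)rectangular plot.

    Non-rectangular plots fall back to their minimum rotated rectangle.
    The axis is oriented toward positive northing (ties: positive
    easting) so the sign of the deviation is reproducible.
    """
    rect = poly.minimum_rotated_rectangle
    coords = np.asarray(rect.exterior.coords)[:4]
    edges = np.diff(np.vstack([coords, coords[:1]]), axis=0)[:2]
    lengths = np.linalg.norm(edges, axis=1)
    u = edges[int(np.argmax(lengths))]
    u = u / np.linalg.norm(u)
    if u[1] < 0 or (u[1] == 0 and u[0] < 0):
        u = -u
    centroid = np.asarray(rect.centroid.coords[0])
    normal = np.array([u[1], -u[0]])  # right of the axis direction
    return u, normal, centroid


def row_deviation(observations: pd.DataFrame, plot_map: PlotMap,
                  x_col: str = "sensor_e", y_col: str = "sensor_n") -> pd.Series:
    """Signed lateral distance from each observation to the long-axis
    centerline of its assigned plot (positive to the right of the axis,
    axis oriented north).  Unassigned observations get NaN.  Exported
    for wobble QC thresholds.
    """
    if "plot_id" not in observations.columns:
        raise PlotMapError("observations must be clipped (plot_id) first")
    dev = np.full(len(observations), np.nan)
    xy = observations[[x_col, y_col]].to_numpy(dtype=float)
    pid = observations["plot_id"].to_numpy(dtype=object)
    for plot in plot_map.plots:
        mask = pid == plot.plot_id
        if not mask.any():
            continue
        _, normal, centroid = _centerline_axes(plot.polygon)
        dev[mask] = (xy[mask] - centroid) @ normal
    return pd.Series(dev, index=observations.index, name="row_deviation_m")
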