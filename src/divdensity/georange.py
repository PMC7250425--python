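"""Occurrence-record cleaning and convex-hull range areas.

Occurrence tables mirror a GBIF export: one row per record with species,
decimal longitude/latitude, and a free-text locality field.  Cleaning
follows two rules: (1) drop records outside the study region polygon,
(2) drop records whose locality text contains 'botanical' or 'garden'
(case-insensitive substring -- a deliberately crude but reproducible filter
for cultivated material; 'Gardenia thicket' would be a false positive).

A clade's occupied area A is the area of the planar convex hull of the
pooled occurrence points of its species, computed after projecting
longitude/latitude to a Lambert cylindrical equal-area projection on a
sphere of radius 6371 km centered on the points' mean longitude:

    x = R * (lon - lon0) * pi/180,   y = R * sin(lat)

The Jacobian of this map is R^2 cos(lat) dlon dlat, the spherical area
element, so planar hull areas are true spherical areas up to the (small)
difference between geodesic and chordal hull edges.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Polygon

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0
#: exact-duplicate tolerance in degrees (GBIF exports are full of duplicates)
DUP_TOL_DEG = 1e-6
#: substrings flagging cultivated-collection records
GARDEN_STRINGS = ("botanical", "garden")

OCCURRENCE_COLUMNS = ["species", "lon", "lat", "locality_text"]


def validate_occurrences(records: pd.DataFrame) -> pd.DataFrame:
    """Check column names and coordinate ranges; returns the frame unchanged."""
    missing = [c for c in ("species", "lon", "lat") if c not in records.columns]
    if missing:
        raise ValueError(f"occurrence table missing columns {missing}")
    if "locality_text" not in records.columns:
        records = records.assign(locality_text="")
    lon = records["lon"].to_numpy(float)
    lat = records["lat"].to_numpy(float)
    bad = ~((lon >= -180) & (lon <= 180) & (lat >= -90) & (lat <= 90))
    if bad.any():
        raise ValueError(f"{bad.sum()} records with out-of-range coordinates")
    return records


def load_occurrences(csv) -> pd.DataFrame:
    return validate_occurrences(pd.read_csv(csv, keep_default_na=False,
                                            na_values=[""],
                                            float_precision="round_trip"))


# ---------------------------------------------------------------------------
# Cleaning filters
# ---------------------------------------------------------------------------

def filter_region(records: pd.DataFrame, region_polygon: Polygon) -> pd.DataFrame:
    """Keep records inside or on the boundary of the study-region polygon."""
    if region_polygon.is_empty:
        raise ValueError("region polygon is empty")
    records = validate_occurrences(records)
    pts = shapely.points(records["lon"].to_numpy(float),
                         records["lat"].to_numpy(float))
    keep = shapely.covers(region_polygon, pts)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("region filter removed %d of %d records", n_drop, len(records))
    if keep.sum() == 0:
        warnings.warn("no occurrence records fall inside the study region")
    return records.loc[keep].reset_index(drop=True)


def filter_garden_records(
    records: pd.DataFrame, text_fields: tuple[str, ...] = ("locality_text",)
) -> pd.DataFrame:
    """Drop records whose text fields contain 'botanical' or 'garden'."""
    records = validate_occurrences(records)
    drop = np.zeros(len(records), dtype=bool)
    for col in text_fields:
        if col not in records.columns:
            continue
        text = records[col].fillna("").astype(str).str.lower()
        for s in GARDEN_STRINGS:
            drop |= text.str.contains(s, regex=False).to_numpy()
    if drop.any():
        logger.info("garden-string filter removed %d records", int(drop.sum()))
    return records.loc[~drop].reset_index(drop=True)


def clean_occurrences(records: pd.DataFrame, region_polygon: Polygon) -> pd.DataFrame:
    """Apply both filters (order is immaterial; the filters commute)."""
    return filter_garden_records(filter_region(records, region_polygon))


# ---------------------------------------------------------------------------
# Hull areas
# ---------------------------------------------------------------------------

@dataclass
class RangeEstimate:
    """Convex-hull range of a set of occurrence points.

    ``area_km2`` is 0 for fewer than 3 distinct points or collinear points;
    ``ok`` is False when the estimate is unusable for density regressions.
    """

    clade_id: str
    n_points: int
    area_km2: float
    hull_vertices: np.ndarray  # (k, 2) projected km coordinates, or empty
    ok: bool = True


def project_equal_area(
    lon: np.ndarray, lat: np.ndarray, lon0: float | None = None
) -> np.ndarray:
    """Lambert cylindrical equal-area (spherical, R = 6371 km) -> (n, 2) km."""
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    if lon0 is None:
        lon0 = float(np.mean(lon)) if lon.size else 0.0
    if lon.size and (lon.max() - lon.min()) > 180:
        warnings.warn(
            "longitudes span more than 180 degrees; hulls are not "
            "antimeridian-aware and the area may be meaningless"
        )
    x = EARTH_RADIUS_KM * np.radians(lon - lon0)
    y = EARTH_RADIUS_KM * np.sin(np.radians(lat))
    return np.column_stack([x, y])


def _dedupe(lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    key = np.round(np.column_stack([lon, lat]) / DUP_TOL_DEG).astype(np.int64)
    _, idx = np.unique(key, axis=0, return_index=True)
    idx.sort()
    return lon[idx], lat[idx]


def hull_area_km2(
    lon, lat, clade_id: str = "", projected: np.ndarray | None = None
) -> RangeEstimate:
    """Equal-area convex hull of lon/lat points (duplicates dropped first).

    Pass ``projected`` to hull pre-projected planar km coordinates instead
    (used by the spatial simulator, where coordinates are cell lengths).
    """
    if projected is None:
        lon = np.asarray(lon, float)
        lat = np.asarray(lat, float)
        lon, lat = _dedupe(lon, lat)
        xy = project_equal_area(lon, lat)
    else:
        xy = np.unique(np.asarray(projected, float), axis=0) \
            if len(projected) else np.empty((0, 2))
    n = len(xy)
    if n < 3:
        return RangeEstimate(clade_id, n, 0.0, np.empty((0, 2)), ok=False)
    hull = MultiPoint(xy).convex_hull
    if hull.geom_type != "Polygon":  # collinear points
        return RangeEstimate(clade_id, n, 0.0, np.empty((0, 2)), ok=False)
    verts = np.asarray(hull.exterior.coords)[:-1]
    return RangeEstimate(clade_id, n, float(hull.area), verts, ok=True)


def clade_range_area(
    tip_set, records: pd.DataFrame, clade_id: str = ""
) -> RangeEstimate:
    """Hull over the pooled occurrence points of all of a clade's species.

    Clades with no records or a degenerate hull come back with ``ok=False``
    and are excluded from density regressions upstream.
    """
    records = validate_occurrences(records)
    sub = records[records["species"].isin(set(tip_set))]
    if len(sub) == 0:
        logger.warning("clade %s has no occurrence records", clade_id or "<anon>")
        return RangeEstimate(clade_id, 0, 0.0, np.empty((0, 2)), ok=False)
    est = hull_area_km2(sub["lon"].to_numpy(float), sub["lat"].to_numpy(float),
                        clade_id=clade_id)
    if not est.ok:
        logger.warning("clade %s has a degenerate hull (area 0)", clade_id or "<anon>")
    return est
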