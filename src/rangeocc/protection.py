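"""Protected-area coverage of a metacommunity.

Two coverage metrics are supported: the proportion of local sites lying inside
protected areas, and the proportion of the metacommunity's spatial extent
(convex hull of the sites) covered by protected areas. Protected areas are
filtered WDPA-style: admissible designation status, no UNESCO Man-and-Biosphere
reserves, and (for the main analysis) established strictly before the first
year of the study's late period. Point records are converted to disks whose
area equals the recorded area.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from shapely.geometry import MultiPoint, Point, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

ADMISSIBLE_STATUS = frozenset({"designated", "inscribed", "established"})


@dataclass
class ProtectedArea:
    geometry: BaseGeometry
    year_established: int
    status: str = "designated"
    mab_flag: bool = False
    name: str = ""
    reported_area_km2: float | None = None


@dataclass
class ProtectionSummary:
    prop_sites_protected: float
    prop_extent_protected: float | None
    cutoff_year: float | None
    n_sites_protected: int
    status: str = "known"  # or 'unknown' for undeterminable studies

    def __post_init__(self) -> None:
        if not 0.0 <= self.prop_sites_protected <= 1.0:
            raise ValueError("prop_sites_protected must be in [0, 1]")


def protected_areas_from_geojson(collection: dict) -> list[ProtectedArea]:
    """Read protected areas from a GeoJSON FeatureCollection dict."""
    pas = []
    for feat in collection.get("features", []):
        props = feat.get("properties", {}) or {}
        pas.append(ProtectedArea(
            geometry=shape(feat["geometry"]),
            year_established=int(props.get("year_established", 0)),
            status=str(props.get("status", "designated")),
            mab_flag=bool(props.get("mab_flag", False)),
            name=str(props.get("name", "")),
            reported_area_km2=props.get("reported_area_km2"),
        ))
    return pas


def filter_protected_areas(
    pas: Iterable[ProtectedArea],
    cutoff_year: float | None = None,
) -> list[ProtectedArea]:
    """Retain admissible protected areas, optionally established before a cutoff.

    Keeps areas with status designated/inscribed/established that are not
    Man-and-Biosphere reserves; with a cutoff (the first late-period year),
    only areas established strictly before it. Point records are buffered to
    disks of the recorded area. Invalid geometries are skipped with a warning.
    Pass ``cutoff_year=None`` (or +inf) for the all-protected-areas variant.
    """
    kept = []
    for pa in pas:
        if pa.status not in ADMISSIBLE_STATUS or pa.mab_flag:
            continue
        if cutoff_year is not None and not pa.year_established < cutoff_year:
            continue
        geom = pa.geometry
        if isinstance(geom, Point):
            area = pa.reported_area_km2 or 0.0
            if area <= 0:
                warnings.warn(f"point protected area {pa.name!r} lacks a recorded area; skipped",
                              stacklevel=2)
                continue
            geom = geom.buffer(math.sqrt(area / math.pi), quad_segs=64)
        if geom.is_empty or not geom.is_valid:
            warnings.warn(f"invalid geometry for protected area {pa.name!r}; skipped",
                          stacklevel=2)
            continue
        kept.append(ProtectedArea(geometry=geom, year_established=pa.year_established,
                                  status=pa.status, mab_flag=pa.mab_flag, name=pa.name,
                                  reported_area_km2=pa.reported_area_km2))
    return kept


def prop_sites_protected(sites: pd.DataFrame, pas: Sequence[ProtectedArea]) -> tuple[float, int]:
    """Proportion (and count) of sites inside protected areas.

    Boundary points count as inside. ``sites`` needs columns x_km, y_km.
    """
    if len(sites) == 0:
        raise ValueError("need at least one site")
    if not pas:
        return 0.0, 0
    union = unary_union([pa.geometry for pa in pas])
    n_in = sum(union.covers(Point(x, y))
               for x, y in zip(sites["x_km"], sites["y_km"]))
    return n_in / len(sites), int(n_in)


def prop_extent_protected(
    sites: pd.DataFrame,
    pas: Sequence[ProtectedArea],
    realm_mask: BaseGeometry | None = None,
) -> float:
    """Proportion of the sites' convex-hull extent covered by protected areas.

    The hull is optionally intersected with a realm mask (e.g. land for
    terrestrial studies) before computing coverage. Falls back to the
    site-based proportion when the hull is degenerate (< 3 non-collinear
    sites).
    """
    pts = MultiPoint([(x, y) for x, y in zip(sites["x_km"], sites["y_km"])])
    hull = pts.convex_hull
    if realm_mask is not None:
        hull = hull.intersection(realm_mask)
    if hull.area <= 0:
        warnings.warn("degenerate convex hull; falling back to the site-based proportion",
                      stacklevel=2)
        return prop_sites_protected(sites, pas)[0]
    if not pas:
        return 0.0
    union = unary_union([pa.geometry for pa in pas])
    return hull.intersection(union).area / hull.area


def fallback_protection_from_description(
    descriptor: str | None,
    extent_km2: float | None = None,
    central_point: tuple[float, float] | None = None,
    pas: Sequence[ProtectedArea] = (),
) -> ProtectionSummary:
    """Protection status for studies without per-site coordinates.

    Regions described as protected overall count as fully protected; regions
    dominated by human activity as unprotected. Otherwise small regions
    (extent <= 10 km²) take the status of their central point; larger regions
    are left 'unknown' and excluded from protection models.
    """
    if descriptor == "protected_overall":
        return ProtectionSummary(1.0, None, None, 1)
    if descriptor == "human_dominated":
        return ProtectionSummary(0.0, None, None, 0)
    if extent_km2 is not None and extent_km2 <= 10.0 and central_point is not None:
        site = pd.DataFrame({"x_km": [central_point[0]], "y_km": [central_point[1]]})
        prop, n = prop_sites_protected(site, pas)
        return ProtectionSummary(prop, None, None, n)
    return ProtectionSummary(0.0, None, None, 0, status="unknown")


@dataclass
class ProtectionResult:
    """Per-study protection metrics bundle."""

    summary: ProtectionSummary
    retained: list[ProtectedArea] = field(default_factory=list)


def summarize_protection(
    sites: pd.DataFrame,
    pas: Iterable[ProtectedArea],
    cutoff_year: float | None,
    realm_mask: BaseGeometry | None = None,
) -> ProtectionResult:
    """Filter protected areas and compute both coverage metrics for one study."""
    retained = filter_protected_areas(pas, cutoff_year=cutoff_year)
    prop_sites, n_in = prop_sites_protected(sites, retained)
    if len(sites) >= 3:
        prop_extent = prop_extent_protected(sites, retained, realm_mask=realm_mask)
    else:
        prop_extent = None
    return ProtectionResult(
        summary=ProtectionSummary(prop_sites, prop_extent, cutoff_year, n_in),
        retained=retained,
    )
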