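"""Species range size from occurrence points.

Range size enters the analysis as a static per-species covariate. Two families
of estimates are provided: area of occupancy (AOO) — the number of occupied
grid cells at 10, 50 and 100 km resolution — and extent of occurrence (EOO) —
the area of an alpha hull (alpha = 6, in coordinate units) for species with
more than three occurrences, or the union of 10-km disks around points for
sparser species. Occurrence records are cleaned beforehand: missing
coordinates, unsuitable record bases, coordinate uncertainty above 100 km,
gazetteer-style flags, and within-species duplicates in 0.01-degree cells are
removed.

Coordinates must be planar and equal-area (synthetic data uses kilometres);
geographic degrees must be projected upstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import Point, Polygon
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

EXCLUDED_BASES = frozenset({"fossil", "material_sample", "living_collection"})
FLAG_COLUMNS = ("flag_centroid", "flag_capital", "flag_institution",
                "flag_equal_latlon", "flag_zero")
AOO_RESOLUTIONS = (10.0, 50.0, 100.0)


@dataclass
class RangeEstimate:
    species_id: str
    aoo_10: int
    aoo_50: int
    aoo_100: int
    eoo_km2: float
    measure_used: str  # 'alpha_hull' or 'buffer'


def clean_occurrences(
    records: pd.DataFrame,
    max_uncertainty_km: float = 100.0,
    dedup_cell: float = 0.01,
    realm_mask: BaseGeometry | None = None,
    mask_keep_inside: bool = True,
) -> pd.DataFrame:
    """Apply the standard occurrence-cleaning filters.

    Removes records with missing coordinates; fossil, material-sample and
    living-collection bases; coordinate uncertainty above 100 km; any raised
    gazetteer flag (centroid/capital/institution/equal-lat-lon/zero); and
    per-species duplicates within ``dedup_cell``-sized cells (first record
    kept). With a ``realm_mask`` polygon, records outside (or inside, for
    ``mask_keep_inside=False``) the mask are removed — e.g. sea records for
    terrestrial species.
    """
    df = records.copy()
    df = df[df["lon"].notna() & df["lat"].notna()]
    if "basis" in df.columns:
        df = df[~df["basis"].isin(EXCLUDED_BASES)]
    if "coord_uncertainty_km" in df.columns:
        df = df[~(df["coord_uncertainty_km"] > max_uncertainty_km)]
    for flag in FLAG_COLUMNS:
        if flag in df.columns:
            df = df[~df[flag].map(lambda v: bool(v) if pd.notna(v) else False)]
    if realm_mask is not None:
        inside = df.apply(lambda r: realm_mask.covers(Point(r["lon"], r["lat"])), axis=1)
        df = df[inside] if mask_keep_inside else df[~inside]
    cells = pd.DataFrame({
        "species_id": df["species_id"],
        "cx": np.floor(df["lon"] / dedup_cell).astype(np.int64),
        "cy": np.floor(df["lat"] / dedup_cell).astype(np.int64),
    }, index=df.index)
    df = df[~cells.duplicated()]
    return df.reset_index(drop=True)


def aoo(points: pd.DataFrame, resolution: float) -> int:
    """Number of distinct occupied grid cells at the given resolution (km)."""
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    if len(points) == 0:
        raise ValueError("need at least one point")
    cx = np.floor(points["lon"].to_numpy(float) / resolution).astype(np.int64)
    cy = np.floor(points["lat"].to_numpy(float) / resolution).astype(np.int64)
    return len(set(zip(cx.tolist(), cy.tolist())))


def _circumradius(pa: np.ndarray, pb: np.ndarray, pc: np.ndarray) -> float:
    a = np.linalg.norm(pb - pc)
    b = np.linalg.norm(pa - pc)
    c = np.linalg.norm(pa - pb)
    area2 = abs((pb[0] - pa[0]) * (pc[1] - pa[1]) - (pc[0] - pa[0]) * (pb[1] - pa[1]))
    if area2 == 0:
        return np.inf
    return a * b * c / (2.0 * area2)


def alpha_hull(points: np.ndarray, alpha: float) -> BaseGeometry:
    """Alpha hull of a 2-D point set as a (multi)polygon.

    Built from the Delaunay triangulation by discarding triangles whose
    circumradius exceeds ``alpha`` (in coordinate units) and taking the union
    of the rest; may be several disjoint polygons. As alpha grows the hull
    converges to the convex hull.
    """
    tri = Delaunay(points)
    keep = []
    for simplex in tri.simplices:
        pa, pb, pc = points[simplex]
        if _circumradius(pa, pb, pc) <= alpha:
            keep.append(Polygon([pa, pb, pc]))
    if not keep:
        from shapely.geometry import GeometryCollection
        return GeometryCollection()
    return unary_union(keep)


def eoo_alpha_hull(points: pd.DataFrame, alpha: float = 6.0) -> float:
    """Extent of occurrence as the alpha-hull area (km²).

    Requires more than three distinct points; raises ``QhullError`` for
    degenerate (e.g. collinear) sets, which callers may catch to fall back to
    :func:`eoo_buffer`.
    """
    pts = points[["lon", "lat"]].drop_duplicates().to_numpy(float)
    if len(pts) <= 3:
        raise ValueError("alpha-hull EOO needs more than three distinct points")
    return alpha_hull(pts, alpha).area


def eoo_buffer(points: pd.DataFrame, radius: float = 10.0, method: str = "union") -> float:
    """Extent of occurrence as buffered points (km²).

    The default is the area of the union of ``radius``-km disks (overlaps not
    double-counted); ``method='sum'`` adds the disk areas arithmetically.
    """
    pts = points[["lon", "lat"]].to_numpy(float)
    if len(pts) == 0:
        raise ValueError("need at least one point")
    if method == "sum":
        return len(np.unique(pts, axis=0)) * math.pi * radius ** 2
    disks = [Point(x, y).buffer(radius, quad_segs=256) for x, y in np.unique(pts, axis=0)]
    return unary_union(disks).area


def estimate_ranges(
    occurrences: pd.DataFrame,
    alpha: float = 6.0,
    resolutions: tuple[float, float, float] = AOO_RESOLUTIONS,
    clean: bool = True,
    **clean_kwargs,
) -> pd.DataFrame:
    """Per-species range estimates: AOO at three resolutions and EOO.

    Returns a DataFrame with columns species_id, aoo_10, aoo_50, aoo_100,
    eoo_km2, measure_used. Species with no clean records are absent from the
    output.
    """
    df = clean_occurrences(occurrences, **clean_kwargs) if clean else occurrences
    rows = []
    for sp, g in df.groupby("species_id", sort=True):
        n_distinct = len(g[["lon", "lat"]].drop_duplicates())
        if n_distinct > 3:
            try:
                eoo = eoo_alpha_hull(g, alpha=alpha)
                measure = "alpha_hull"
            except (QhullError, ValueError):
                eoo = eoo_buffer(g)
                measure = "buffer"
        else:
            eoo = eoo_buffer(g)
            measure = "buffer"
        rows.append({
            "species_id": sp,
            "aoo_10": aoo(g, resolutions[0]),
            "aoo_50": aoo(g, resolutions[1]),
            "aoo_100": aoo(g, resolutions[2]),
            "eoo_km2": eoo,
            "measure_used": measure,
        })
    return pd.DataFrame(rows)


def log10_center(values: pd.Series | np.ndarray) -> tuple[np.ndarray, float]:
    """Log10-transform range sizes and centre on the mean log10 value.

    Returns (centered values, centering constant); the constant allows axes
    to be back-transformed to raw range sizes.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0):
        raise ValueError("range sizes must be positive")
    logs = np.log10(v)
    center = float(logs.mean())
    return logs - center, center


def gbif_support_filter(
    assemblage_counts: pd.Series,
    occurrence_counts: pd.Series,
    factor: float = 5.0,
) -> pd.Index:
    """Species whose occurrence support is at least ``factor`` x the assemblage count.

    Both inputs are per-species occupied 0.01-degree cell counts; species
    missing from ``occurrence_counts`` count as zero. Used as a sensitivity
    filter against circularity between the survey and occurrence datasets.
    """
    occ = occurrence_counts.reindex(assemblage_counts.index).fillna(0.0)
    keep = occ >= factor * assemblage_counts
    return assemblage_counts.index[keep]


def study_inclusion_filter(
    n_sites_per_year: dict[int, int] | pd.Series,
    year_span: float,
    n_species_with_ranges: int,
    min_sites: int = 4,
    min_span: float = 10.0,
    min_species: int = 10,
) -> bool:
    """Inclusion rule: enough sites each year, a long enough span, enough species.

    A study enters the analysis only with at least ``min_sites`` sites per
    retained year, a span of at least ``min_span`` years, and at least
    ``min_species`` species with range estimates.
    """
    counts = pd.Series(n_sites_per_year)
    return bool(
        (counts >= min_sites).all()
        and year_span >= min_span
        and n_species_with_ranges >= min_species
    )
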