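"""Survey standardization: site matching across years and effort equalization.

Surveys of a metacommunity rarely revisit exactly the same set of sites every
year. To compare occupancy across time, the study extent is subdivided into
grid cells (resolution = 1/5 of the mean of the x and y spans), cells with
consistent sampling are retained, a pair of reference years at least a decade
apart with near-maximal spatial overlap is chosen, and only years covering
more than 90% of the reference cells (weighted by their share of sites) are
kept. A stricter sensitivity variant matches sites by exact coordinates
instead of shared cells. Finally, within-site sampling effort is equalized by
sample-based rarefaction to one combined sample per site and year.

Site identity for matching purposes is the coordinate pair: two rows at the
same location are the same site.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

Cell = tuple[int, int]


class DegenerateExtentError(ValueError):
    """All sites share a single coordinate: no grid can be defined."""


class StudyDroppedError(ValueError):
    """The study fails an inclusion rule (no eligible year pair, empty cells...)."""


@dataclass(frozen=True)
class GridAssignment:
    resolution: float
    origin: tuple[float, float]
    n_cells: tuple[int, int]

    def cell_of(self, x: float, y: float) -> Cell:
        cx = int(np.floor((x - self.origin[0]) / self.resolution))
        cy = int(np.floor((y - self.origin[1]) / self.resolution))
        # the maximum-coordinate boundary belongs to the last cell
        return (min(cx, self.n_cells[0] - 1), min(cy, self.n_cells[1] - 1))

    def cells(self, df: pd.DataFrame) -> pd.Series:
        return pd.Series(
            [self.cell_of(x, y) for x, y in zip(df["x_km"], df["y_km"])],
            index=df.index,
        )


@dataclass
class StandardizedStudy:
    data: pd.DataFrame
    mode: str
    reference_pair: tuple[int, int]
    retained_years: tuple[int, ...]
    retained_sites: tuple[str, ...]
    assignment: GridAssignment | None = None
    audit: list[dict] = field(default_factory=list)


def _locations(df: pd.DataFrame) -> pd.Series:
    """Location key per row: the exact coordinate pair."""
    return pd.Series(list(zip(df["x_km"].round(9), df["y_km"].round(9))), index=df.index)


def assign_grid_cells(study: pd.DataFrame) -> GridAssignment:
    """Grid over the study extent at 1/5 of the mean coordinate span."""
    xs, ys = study["x_km"].to_numpy(float), study["y_km"].to_numpy(float)
    x_span, y_span = xs.max() - xs.min(), ys.max() - ys.min()
    if x_span == 0 and y_span == 0:
        raise DegenerateExtentError("all sites share one coordinate")
    resolution = (x_span + y_span) / 2 / 5
    nx = max(1, int(np.ceil(x_span / resolution))) if x_span > 0 else 1
    ny = max(1, int(np.ceil(y_span / resolution))) if y_span > 0 else 1
    return GridAssignment(resolution=resolution, origin=(xs.min(), ys.min()),
                          n_cells=(nx, ny))


def filter_cells(assignment: GridAssignment, study: pd.DataFrame) -> set[Cell]:
    """Cells surveyed in every year, plus cells with above-average site counts.

    The union reading: a cell is retained if it contains surveys across all
    years OR holds more than half the mean number of sites per occupied cell.
    """
    df = study.copy()
    df["cell"] = assignment.cells(df)
    df["loc"] = _locations(df)
    years = df["year"].unique()
    by_cell_year = df.groupby("cell")["year"].nunique()
    all_years = set(by_cell_year[by_cell_year == len(years)].index)
    sites_per_cell = df.drop_duplicates(["cell", "loc"]).groupby("cell").size()
    high_count = set(sites_per_cell[sites_per_cell > sites_per_cell.mean() / 2].index)
    retained = all_years | high_count
    if not retained:
        raise StudyDroppedError("no cells retained")
    return retained


def _pair_cooccurrence_grid(df: pd.DataFrame, year_a: int, year_b: int) -> int:
    """Sites co-occurring in shared cells between two years (matched pairs)."""
    a = df[df["year"] == year_a].drop_duplicates(["cell", "loc"]).groupby("cell").size()
    b = df[df["year"] == year_b].drop_duplicates(["cell", "loc"]).groupby("cell").size()
    shared = a.index.intersection(b.index)
    return int(np.minimum(a[shared], b[shared]).sum())


def select_reference_year_pair(
    study: pd.DataFrame,
    assignment: GridAssignment,
    retained_cells: set[Cell],
    min_interval: int = 10,
) -> tuple[int, int]:
    """Pick the reference year pair: near-maximal overlap, maximal duration.

    Among year pairs at least ``min_interval`` years apart, pairs whose
    cell-matched site count exceeds 90% of the maximum are eligible; the
    eligible pair with the longest duration wins, ties broken by the earliest
    first year.
    """
    df = study.copy()
    df["cell"] = assignment.cells(df)
    df["loc"] = _locations(df)
    df = df[df["cell"].isin(retained_cells)]
    years = sorted(df["year"].unique())
    pairs = [(a, b) for a, b in itertools.combinations(years, 2) if b - a >= min_interval]
    if not pairs:
        raise StudyDroppedError(f"no year pair spans >= {min_interval} years")
    counts = {p: _pair_cooccurrence_grid(df, *p) for p in pairs}
    max_count = max(counts.values())
    if max_count == 0:
        raise StudyDroppedError("no co-occurring sites in any eligible year pair")
    eligible = [p for p in pairs if counts[p] > 0.9 * max_count]
    return max(eligible, key=lambda p: (p[1] - p[0], -p[0]))


def filter_years_by_coverage(
    study: pd.DataFrame,
    assignment: GridAssignment,
    reference_pair: tuple[int, int],
    retained_cells: set[Cell],
) -> tuple[tuple[int, ...], set[Cell]]:
    """Keep years covering > 90% of the reference cells, weighted by sites.

    Selected cells are those surveyed in both reference years; each carries a
    weight equal to its share of the reference-pair sites. A year is retained
    when the cells it covers carry total weight > 0.9. Both reference years
    are always retained. Returns (years, selected cells).
    """
    df = study.copy()
    df["cell"] = assignment.cells(df)
    df["loc"] = _locations(df)
    df = df[df["cell"].isin(retained_cells)]
    ya, yb = reference_pair
    in_a = set(df.loc[df["year"] == ya, "cell"])
    in_b = set(df.loc[df["year"] == yb, "cell"])
    selected = in_a & in_b
    if not selected:
        raise StudyDroppedError("reference years share no cells")
    ref = df[df["year"].isin(reference_pair) & df["cell"].isin(selected)]
    w = ref.drop_duplicates(["year", "cell", "loc"]).groupby("cell").size()
    w = w / w.sum()
    retained = []
    for year, g in df.groupby("year"):
        covered = set(g["cell"]) & selected
        if year in reference_pair or w.reindex(list(covered)).fillna(0).sum() > 0.9:
            retained.append(int(year))
    return tuple(sorted(retained)), selected


def exclude_sparse_years(
    site_counts: dict[int, int],
    reference_pair: tuple[int, int] | None = None,
    min_span: int = 10,
) -> tuple[int, ...]:
    """Drop years with fewer than half the mean site count.

    The exclusion is skipped (with a warning) if it would shrink the remaining
    span below ``min_span`` years. The reference years are never dropped.
    """
    years = sorted(site_counts)
    mean = np.mean([site_counts[y] for y in years])
    keep = [y for y in years
            if site_counts[y] >= mean / 2
            or (reference_pair is not None and y in reference_pair)]
    if keep and keep[-1] - keep[0] >= min_span:
        return tuple(keep)
    if keep != years:
        warnings.warn("sparse-year exclusion skipped: remaining span would be "
                      f"< {min_span} years", stacklevel=2)
    return tuple(years)


def rarefy_sampling_effort(study: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Equalize within-site-year effort to one combined sample.

    Selects n_min samples (the minimum distinct sample count over site-years)
    uniformly without replacement in each site-year and unions their species,
    yielding one combined sample per site and year (sample_id 'combined').
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 97]))
    n_min = int(study.groupby(["site_id", "year"])["sample_id"].nunique().min())
    parts = []
    for (site, year), g in study.groupby(["site_id", "year"], sort=True):
        samples = sorted(g["sample_id"].unique())
        if len(samples) > n_min:
            samples = [samples[i] for i in
                       sorted(rng.choice(len(samples), size=n_min, replace=False))]
        sub = g[g["sample_id"].isin(samples)].drop_duplicates("species_id").copy()
        sub["sample_id"] = "combined"
        parts.append(sub)
    return pd.concat(parts, ignore_index=True)


def keep_modal_method(study: pd.DataFrame) -> tuple[pd.DataFrame, str | None]:
    """Keep only rows collected with the most widely used methodology.

    Uses the optional ``method`` column: the method applied at the greatest
    number of sites wins, ties broken lexicographically.
    """
    if "method" not in study.columns or study["method"].nunique() <= 1:
        return study, None
    per_method = (study.assign(loc=_locations(study))
                       .drop_duplicates(["method", "loc"])
                       .groupby("method").size())
    best = per_method[per_method == per_method.max()].index.min()
    return study[study["method"] == best].copy(), str(best)


def _pair_cooccurrence_exact(df: pd.DataFrame, year_a: int, year_b: int) -> int:
    a = set(df.loc[df["year"] == year_a, "loc"])
    b = set(df.loc[df["year"] == year_b, "loc"])
    return len(a & b)


def exact_location_filter(study: pd.DataFrame, min_interval: int = 10) -> StandardizedStudy:
    """Sensitivity variant matching sites by identical coordinates.

    The reference pair maximizes duration among pairs whose same-location site
    count exceeds 90% of the maximum; the shared sites of that pair are kept,
    along with every year that sampled all of them.
    """
    df, modal = keep_modal_method(study)
    df = df.copy()
    df["loc"] = _locations(df)
    audit = []
    if modal is not None:
        audit.append({"step": "keep_modal_method", "kept_method": modal})
    years = sorted(df["year"].unique())
    pairs = [(a, b) for a, b in itertools.combinations(years, 2) if b - a >= min_interval]
    if not pairs:
        raise StudyDroppedError(f"no year pair spans >= {min_interval} years")
    counts = {p: _pair_cooccurrence_exact(df, *p) for p in pairs}
    max_count = max(counts.values())
    if max_count == 0:
        raise StudyDroppedError("no same-location sites in any eligible year pair")
    eligible = [p for p in pairs if counts[p] > 0.9 * max_count]
    pair = max(eligible, key=lambda p: (p[1] - p[0], -p[0]))
    shared = (set(df.loc[df["year"] == pair[0], "loc"])
              & set(df.loc[df["year"] == pair[1], "loc"]))
    retained_years = []
    for year, g in df.groupby("year"):
        if shared <= set(g["loc"]):
            retained_years.append(int(year))
    out = df[df["year"].isin(retained_years) & df["loc"].isin(shared)].drop(columns="loc")
    audit.append({"step": "exact_location_filter", "reference_pair": list(pair),
                  "n_shared_sites": len(shared), "retained_years": sorted(retained_years)})
    return StandardizedStudy(
        data=out.reset_index(drop=True), mode="exact", reference_pair=pair,
        retained_years=tuple(sorted(retained_years)),
        retained_sites=tuple(sorted(out["site_id"].unique())),
        assignment=None, audit=audit,
    )


def standardize_study(
    study: pd.DataFrame,
    mode: str = "grid",
    seed: int = 0,
    min_interval: int = 10,
) -> StandardizedStudy:
    """Full standardization of one study (grid-based or exact-location).

    Steps: modal-method pre-filter; grid assignment and cell filtering; choice
    of a reference year pair; year filtering by weighted cell coverage;
    sparse-year exclusion; within-site effort rarefaction.
    """
    if mode == "exact":
        std = exact_location_filter(study, min_interval=min_interval)
        rarefied = rarefy_sampling_effort(std.data, seed=seed)
        return StandardizedStudy(data=rarefied, mode="exact",
                                 reference_pair=std.reference_pair,
                                 retained_years=std.retained_years,
                                 retained_sites=std.retained_sites,
                                 assignment=None, audit=std.audit)
    if mode != "grid":
        raise ValueError("mode must be 'grid' or 'exact'")
    df, modal = keep_modal_method(study)
    audit = []
    if modal is not None:
        audit.append({"step": "keep_modal_method", "kept_method": modal})
    assignment = assign_grid_cells(df)
    retained_cells = filter_cells(assignment, df)
    audit.append({"step": "filter_cells", "n_cells_retained": len(retained_cells)})
    pair = select_reference_year_pair(df, assignment, retained_cells,
                                      min_interval=min_interval)
    years, selected = filter_years_by_coverage(df, assignment, pair, retained_cells)
    audit.append({"step": "select_reference_year_pair", "reference_pair": list(pair),
                  "retained_years": list(years), "n_selected_cells": len(selected)})
    sub = df[df["year"].isin(years)].copy()
    sub["cell"] = assignment.cells(sub)
    sub = sub[sub["cell"].isin(selected)].drop(columns="cell")
    sub["loc"] = _locations(sub)
    counts = {int(y): g["loc"].nunique() for y, g in sub.groupby("year")}
    final_years = exclude_sparse_years(counts, reference_pair=pair, min_span=min_interval)
    if set(final_years) != set(years):
        audit.append({"step": "exclude_sparse_years",
                      "dropped": sorted(set(years) - set(final_years))})
    sub = sub[sub["year"].isin(final_years)].drop(columns="loc")
    rarefied = rarefy_sampling_effort(sub, seed=seed)
    return StandardizedStudy(
        data=rarefied.reset_index(drop=True), mode="grid", reference_pair=pair,
        retained_years=tuple(sorted(final_years)),
        retained_sites=tuple(sorted(rarefied["site_id"].unique())),
        assignment=assignment, audit=audit,
    )
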