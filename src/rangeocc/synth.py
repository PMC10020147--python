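"""Synthetic metacommunities, occurrence clouds and protected areas.

Every downstream stage of the pipeline (standardization, occupancy change,
range-size estimation, protection metrics, hierarchical model) is exercised on
data produced here, with the generating parameters retained as ground truth.

The generative model mirrors the statistical model fitted downstream: the
sign·sqrt-transformed occupancy change of species *j* in study *i* is

    y_ij = (beta0 + u0i) + (beta1 + u1i) * range_j + Normal(0, sigma_i),
    log(sigma_i) = eta0 + eta1 * log(nsamp_i),

where ``range_j`` is the species' log10 range size centred on the global mean
and ``nsamp_i`` is the number of samples per period. The raw occupancy change
is the back-transform sign(y)·y², realized as per-sample presences so that
empirical occupancies match the targets to within 1/nsamp.

Coordinates are planar kilometres throughout: synthetic data deliberately
avoids geodesy so that grid cells, buffers and hull areas are exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .occupancy import balance_period_years, split_periods
from .protection import ProtectedArea

REALMS = ("terrestrial", "freshwater", "marine")
_TAXA = ("birds", "fish", "invertebrates", "plants", "mammals", "amphibians and reptiles")
_REGIONS = {
    "terrestrial": ("Europe", "North America", "Asia"),
    "freshwater": ("Europe", "North America", "Australia"),
    "marine": ("Atlantic Ocean", "Pacific Ocean", "other oceans"),
}

CONTAMINANT_KINDS = ("missing_coords", "high_uncertainty", "bad_basis", "flagged", "duplicate")


@dataclass(frozen=True)
class SynthConfig:
    """Generating parameters for a synthetic metadataset.

    ``beta0``/``beta1`` are the global intercept and slope on the transformed
    occupancy-change scale; ``tau0``/``tau1`` the SDs of study-level intercept
    and slope deviations; ``eta0``/``eta1`` the coefficients of the log-linear
    variance submodel log(sigma_i) = eta0 + eta1*log(nsamp_i).

    ``n_sites`` is a baseline: the realized number of sites varies across
    studies (uniform on a log scale, roughly n_sites/3 .. 3*n_sites, floor 4)
    so that the variance submodel slope eta1 is identifiable.
    """

    n_studies: int = 30
    n_species_per_study: int = 50
    n_sites: int = 12
    n_years: int = 10
    year_span: int = 18
    start_year: int = 1990
    beta0: float = 0.0
    beta1: float = 0.02
    tau0: float = 0.05
    tau1: float = 0.01
    eta0: float = -1.0
    eta1: float = -0.5
    range_size_log10_mean: float = 1.5
    range_size_log10_sd: float = 0.6
    protected_fraction: float = 0.25
    coordinate_extent: float = 100.0
    site_turnover: float = 0.0
    samples_per_site_year: int = 1
    vary_n_sites: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_studies", "n_species_per_study", "n_sites", "n_years",
                     "samples_per_site_year"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.protected_fraction <= 1.0:
            raise ValueError("protected_fraction must be in [0, 1]")
        if self.tau0 < 0 or self.tau1 < 0:
            raise ValueError("tau0 and tau1 must be >= 0")
        if self.n_years >= 2 and self.year_span < 10:
            raise ValueError("year_span must be >= 10 for a valid time series")


@dataclass
class GroundTruth:
    """Generating quantities retained for parameter-recovery checks."""

    config: SynthConfig
    studies: pd.DataFrame   # study_id, realm, taxon, region, u0, u1, true_slope, sigma, nsamp, n_sites
    species: pd.DataFrame   # study_id, species_id, cellcount, log10_range, range_centered,
                            # mu, y_target, delta_target, p_early, p_late, clipped
    n_clipped: int = 0
    extras: dict = field(default_factory=dict)


def _study_rng(seed: int, study_index: int) -> np.random.Generator:
    # one stream per study: reproducible under any execution order
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(study_index)]))


def _study_years(config: SynthConfig) -> list[int]:
    if config.n_years == 1:
        return [config.start_year]
    offsets = np.round(np.linspace(0.0, config.year_span, config.n_years)).astype(int)
    return sorted(set(int(config.start_year + o) for o in offsets))


def generate_metadataset(config: SynthConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a collection of synthetic metacommunity survey tables.

    Returns a long-format survey table (one row per presence) covering all
    studies, plus the :class:`GroundTruth` with study- and species-level
    generating quantities.
    """
    years = _study_years(config)
    assignment = balance_period_years(split_periods(years)) if len(years) >= 2 else None

    # Draw study structure and species range sizes first: the range covariate
    # is centred on the *global* mean log10 range size, as in the fitted model.
    study_rows = []
    cellcounts: list[np.ndarray] = []
    site_frames: list[pd.DataFrame] = []
    for i in range(config.n_studies):
        rng = _study_rng(config.seed, i)
        u0 = rng.normal(0.0, config.tau0) if config.tau0 > 0 else 0.0
        u1 = rng.normal(0.0, config.tau1) if config.tau1 > 0 else 0.0
        if config.vary_n_sites:
            n_sites = max(4, int(round(config.n_sites * 10 ** rng.uniform(-0.5, 0.5))))
        else:
            n_sites = config.n_sites
        realm = REALMS[i % len(REALMS)]
        taxon = _TAXA[i % len(_TAXA)]
        region = _REGIONS[realm][i % len(_REGIONS[realm])]
        xy = rng.uniform(0.0, config.coordinate_extent, size=(n_sites, 2))
        site_frames.append(pd.DataFrame({
            "study_id": f"study_{i:03d}",
            "site_id": [f"site_{s:03d}" for s in range(n_sites)],
            "x_km": xy[:, 0], "y_km": xy[:, 1],
        }))
        draw = rng.normal(config.range_size_log10_mean, config.range_size_log10_sd,
                          size=config.n_species_per_study)
        draw = np.clip(draw, config.range_size_log10_mean - 2.5 * config.range_size_log10_sd,
                       config.range_size_log10_mean + 2.5 * config.range_size_log10_sd)
        counts = np.clip(np.round(10.0 ** draw), 1, 5000).astype(int)
        cellcounts.append(counts)
        study_rows.append({"study_id": f"study_{i:03d}", "realm": realm, "taxon": taxon,
                           "region": region, "u0": u0, "u1": u1,
                           "true_slope": config.beta1 + u1, "n_sites": n_sites})
    studies = pd.DataFrame(study_rows)

    all_log10 = np.log10(np.concatenate(cellcounts).astype(float))
    global_mean_log10 = float(all_log10.mean())

    survey_parts: list[pd.DataFrame] = []
    species_rows = []
    n_clipped = 0
    for i, srow in studies.iterrows():
        # stream independent of the structural draws above
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), int(i), 1]))
        n_sites = int(srow["n_sites"])
        sites = site_frames[i]

        if assignment is not None:
            early_years, late_years = list(assignment.early_years), list(assignment.late_years)
        else:
            early_years, late_years = [years[0]], []
        other_years = [y for y in years if y not in early_years and y not in late_years]

        # surveyed (site, year) grid, with optional turnover
        surveyed: dict[int, np.ndarray] = {}
        for y in years:
            idx = np.arange(n_sites)
            if config.site_turnover > 0 and len(idx) > 4:
                keep = max(4, int(round(n_sites * (1.0 - config.site_turnover))))
                idx = np.sort(rng.choice(idx, size=keep, replace=False))
            surveyed[y] = idx

        early_samples = [(s, y) for y in early_years for s in surveyed[y]]
        late_samples = [(s, y) for y in late_years for s in surveyed[y]]
        nsamp = min(len(early_samples), len(late_samples)) if late_samples else len(early_samples)
        sigma = math.exp(config.eta0 + config.eta1 * math.log(nsamp))

        counts = cellcounts[i]
        log10_range = np.log10(counts.astype(float))
        range_centered = log10_range - global_mean_log10
        mu = (config.beta0 + srow["u0"]) + (config.beta1 + srow["u1"]) * range_centered
        y_target = mu + rng.normal(0.0, sigma, size=len(counts))
        clipped = np.abs(y_target) > 1.0
        y_target = np.clip(y_target, -1.0, 1.0)
        delta = np.sign(y_target) * y_target ** 2
        p_early = rng.uniform(0.15, 0.85, size=len(counts))
        p_late = p_early + delta
        out = (p_late < 0.0) | (p_late > 1.0)
        p_late = np.clip(p_late, 0.0, 1.0)
        clipped |= out
        delta = p_late - p_early
        y_target = np.sign(delta) * np.sqrt(np.abs(delta))
        n_clipped += int(clipped.sum())

        presences: list[tuple[str, int, str]] = []  # (site_id, year, species_id)
        sample_ids = [f"s{k+1}" for k in range(config.samples_per_site_year)]
        for j in range(len(counts)):
            sp = f"{srow['study_id']}_sp{j:03d}"
            for samples, p in ((early_samples, p_early[j]), (late_samples, p_late[j])):
                if not samples:
                    continue
                k = int(round(p * len(samples)))
                if k > 0:
                    chosen = rng.choice(len(samples), size=k, replace=False)
                    for c in chosen:
                        s, y = samples[c]
                        presences.append((f"site_{s:03d}", y, sp))
            p_mid = 0.5 * (p_early[j] + p_late[j])
            for y in other_years:
                for s in surveyed[y]:
                    if rng.random() < p_mid:
                        presences.append((f"site_{s:03d}", y, sp))

        if presences:
            part = pd.DataFrame(presences, columns=["site_id", "year", "species_id"])
            # replicate presences across within-site-year samples (all samples
            # record the species, so effort rarefaction is exact on defaults)
            part = part.merge(pd.DataFrame({"sample_id": sample_ids}), how="cross")
            part["study_id"] = srow["study_id"]
            part = part.merge(sites, on=["study_id", "site_id"])
            part["realm"] = srow["realm"]
            part["taxon"] = srow["taxon"]
            part["region"] = srow["region"]
            survey_parts.append(part)

        sp_ids = [f"{srow['study_id']}_sp{j:03d}" for j in range(len(counts))]
        species_rows.append(pd.DataFrame({
            "study_id": srow["study_id"], "species_id": sp_ids, "cellcount": counts,
            "log10_range": log10_range, "range_centered": range_centered, "mu": mu,
            "y_target": y_target, "delta_target": delta,
            "p_early": p_early, "p_late": p_late, "clipped": clipped,
        }))
        studies.loc[i, "sigma"] = sigma
        studies.loc[i, "nsamp"] = nsamp

    studies["nsamp"] = studies["nsamp"].astype(int)
    surveys = pd.concat(survey_parts, ignore_index=True)[
        ["study_id", "site_id", "x_km", "y_km", "year", "sample_id", "species_id",
         "realm", "taxon", "region"]
    ].sort_values(["study_id", "year", "site_id", "sample_id", "species_id"], ignore_index=True)
    truth = GroundTruth(config=config, studies=studies,
                        species=pd.concat(species_rows, ignore_index=True),
                        n_clipped=n_clipped,
                        extras={"global_mean_log10_range": global_mean_log10,
                                "years": years})
    return surveys, truth


def study_sites(surveys: pd.DataFrame, study_id: str) -> pd.DataFrame:
    """Unique site coordinates of one study from a survey table."""
    sub = surveys.loc[surveys["study_id"] == study_id, ["site_id", "x_km", "y_km"]]
    return sub.drop_duplicates("site_id").reset_index(drop=True)


def generate_occurrences(
    range_sizes: Mapping[str, int],
    resolution: float = 10.0,
    seed: int = 0,
    contaminant_fraction: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate occurrence points occupying exactly the target number of cells.

    Parameters
    ----------
    range_sizes
        Mapping species_id -> target number of occupied ``resolution``-sized
        grid cells (the species' true AOO at that resolution).
    contaminant_fraction
        Fraction of additional dirty records per species (missing coordinates,
        uncertainty > 100 km, fossil basis, flagged, exact duplicates), each
        flagged in the returned ground-truth table.

    Returns
    -------
    (occurrences, truth) where truth has one row per record with its
    contaminant kind ('' for clean records).
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    for sp, n in range_sizes.items():
        if n < 1:
            raise ValueError(f"target cell count for {sp} must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7_777]))
    max_cells = max(range_sizes.values())
    grid_dim = int(math.ceil(math.sqrt(2.5 * max_cells))) + 1
    rows = []
    truth_rows = []
    rec = 0
    for sp in sorted(range_sizes):
        n_cells = int(range_sizes[sp])
        chosen = rng.choice(grid_dim * grid_dim, size=n_cells, replace=False)
        cx, cy = chosen % grid_dim, chosen // grid_dim
        # one interior point per chosen cell; margin keeps it off boundaries
        px = (cx + rng.uniform(0.1, 0.9, n_cells)) * resolution
        py = (cy + rng.uniform(0.1, 0.9, n_cells)) * resolution
        extra = rng.random(n_cells) < 0.15  # some cells get a second point
        px = np.concatenate([px, (cx[extra] + rng.uniform(0.1, 0.9, extra.sum())) * resolution])
        py = np.concatenate([py, (cy[extra] + rng.uniform(0.1, 0.9, extra.sum())) * resolution])
        clean = pd.DataFrame({
            "record_id": np.arange(rec, rec + len(px)),
            "species_id": sp, "lon": px, "lat": py,
            "coord_uncertainty_km": rng.uniform(0.0, 50.0, len(px)),
            "basis": "human_observation",
        })
        rec += len(px)
        rows.append(clean)
        truth_rows.append(pd.DataFrame({"record_id": clean["record_id"],
                                        "species_id": sp, "contaminant": ""}))
        n_bad = int(round(contaminant_fraction * len(px)))
        if n_bad:
            bad_rows = []
            for b in range(n_bad):
                kind = CONTAMINANT_KINDS[b % len(CONTAMINANT_KINDS)]
                src = int(rng.integers(0, len(px)))
                row = {"record_id": rec, "species_id": sp,
                       "lon": float(px[src]), "lat": float(py[src]),
                       "coord_uncertainty_km": float(rng.uniform(0.0, 50.0)),
                       "basis": "human_observation"}
                if kind == "missing_coords":
                    row["lon"] = row["lat"] = np.nan
                elif kind == "high_uncertainty":
                    row["coord_uncertainty_km"] = float(rng.uniform(101.0, 500.0))
                elif kind == "bad_basis":
                    row["basis"] = rng.choice(["fossil", "material_sample", "living_collection"])
                elif kind == "flagged":
                    flag = rng.choice(["flag_centroid", "flag_capital", "flag_institution",
                                       "flag_equal_latlon", "flag_zero"])
                    row[flag] = True
                # 'duplicate': exact copy of a clean record's coordinates
                bad_rows.append(row)
                truth_rows.append(pd.DataFrame({"record_id": [rec], "species_id": [sp],
                                                "contaminant": [kind]}))
                rec += 1
            rows.append(pd.DataFrame(bad_rows))
    occ = pd.concat(rows, ignore_index=True)
    for flag in ("flag_centroid", "flag_capital", "flag_institution",
                 "flag_equal_latlon", "flag_zero"):
        if flag not in occ.columns:
            occ[flag] = False
        occ[flag] = occ[flag].map(lambda v: bool(v) if pd.notna(v) else False)
    truth = pd.concat(truth_rows, ignore_index=True)
    return occ.reset_index(drop=True), truth


def generate_protected_areas(
    sites: pd.DataFrame,
    protected_fraction: float,
    establishment_year: int = 1980,
    seed: int = 0,
) -> list[ProtectedArea]:
    """Generate protected-area polygons covering a target fraction of sites.

    The realized covered fraction equals round(f * n_sites) / n_sites, i.e.
    within 1/n_sites of the target. Polygons are small squares around chosen
    sites (guaranteed not to contain any other site), or a single buffered
    convex hull when the whole metacommunity is protected.
    """
    from shapely.geometry import MultiPoint, box

    if not 0.0 <= protected_fraction <= 1.0:
        raise ValueError("protected_fraction must be in [0, 1]")
    n = len(sites)
    if n == 0 or protected_fraction == 0.0:
        return []
    xy = sites[["x_km", "y_km"]].to_numpy(float)
    if protected_fraction >= 1.0:
        geom = MultiPoint([tuple(p) for p in xy]).convex_hull.buffer(1.0)
        return [ProtectedArea(geometry=geom, year_established=establishment_year,
                              status="designated", mab_flag=False, name="pa_all")]
    k = int(round(protected_fraction * n))
    if k == 0:
        return []
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 13_131]))
    chosen = rng.choice(n, size=k, replace=False)
    # half-width below half the minimum inter-site distance: covers one site only
    from scipy.spatial.distance import pdist
    min_d = float(pdist(xy).min()) if n > 1 else 1.0
    h = min(5.0, 0.45 * min_d) if min_d > 0 else 1e-3
    pas = []
    for idx, c in enumerate(sorted(chosen)):
        x, y = xy[c]
        pas.append(ProtectedArea(geometry=box(x - h, y - h, x + h, y + h),
                                 year_established=establishment_year,
                                 status="designated", mab_flag=False,
                                 name=f"pa_{idx:03d}"))
    return pas


def protected_areas_to_geojson(pas: Sequence[ProtectedArea]) -> dict:
    """Serialize protected areas as a GeoJSON FeatureCollection dict."""
    from shapely.geometry import mapping

    return {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(pa.geometry),
             "properties": {"name": pa.name, "status": pa.status,
                            "year_established": pa.year_established,
                            "mab_flag": pa.mab_flag,
                            "reported_area_km2": pa.geometry.area}}
            for pa in pas
        ],
    }
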