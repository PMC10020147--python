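"""Occupancy change between early and late periods of a metacommunity series.

A study's sampled years are split at the midpoint of the time span into an
early and a late period, balanced to the same number of years. Per-species
occupancy in a period is the fraction of samples (site-year observation
events) in which the species is present. The change (late minus early) lies in
[-1, 1] and is sign·sqrt-transformed before modelling to decompress its
leptokurtic distribution around zero.

Variation in the number of sites across years is handled by sample-based
rarefaction: each of ``n_iter`` iterations draws the minimum per-year site
count from every year, without replacement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DYNAMICS_CLASSES = ("lost", "gained", "persist_up", "persist_down", "persist_stable")


@dataclass(frozen=True)
class PeriodAssignment:
    middle_year: float
    early_years: tuple[int, ...]
    late_years: tuple[int, ...]

    @property
    def n_years_per_period(self) -> int:
        return min(len(self.early_years), len(self.late_years))


def split_periods(years) -> PeriodAssignment:
    """Split sorted calendar years into early/late periods at the span midpoint.

    A two-year series uses first and last year directly. Otherwise years
    strictly before the midpoint form the early period and years strictly
    after it the late period; a year falling exactly on the midpoint belongs
    to neither.
    """
    ys = sorted(set(int(y) for y in years))
    if len(ys) < 2:
        raise ValueError("need at least two sampled years")
    if ys[-1] - ys[0] < 10:
        raise ValueError("time span must be at least 10 years")
    if len(ys) == 2:
        return PeriodAssignment(middle_year=(ys[0] + ys[1]) / 2,
                                early_years=(ys[0],), late_years=(ys[1],))
    middle = (ys[0] + ys[-1]) / 2
    early = tuple(y for y in ys if y < middle)
    late = tuple(y for y in ys if y > middle)
    if not early or not late:
        raise ValueError("a period is empty after splitting")
    return PeriodAssignment(middle_year=middle, early_years=early, late_years=late)


def balance_period_years(assignment: PeriodAssignment) -> PeriodAssignment:
    """Equalize the number of years per period.

    The early period keeps its earliest k years and the late period its latest
    k years (k = the smaller period size), maximizing the duration between
    the retained observations.
    """
    k = assignment.n_years_per_period
    if k < 1:
        raise ValueError("both periods must be nonempty")
    return PeriodAssignment(
        middle_year=assignment.middle_year,
        early_years=tuple(sorted(assignment.early_years)[:k]),
        late_years=tuple(sorted(assignment.late_years)[-k:]),
    )


def rarefy_sites(
    sites_per_year: dict[int, list[str]],
    n_iter: int = 200,
    seed: int = 0,
) -> list[dict[int, tuple[str, ...]]]:
    """Draw equal-size site subsets per year, repeated ``n_iter`` times.

    Each iteration samples m = min over years of the per-year site count,
    uniformly without replacement from every year's site list.
    """
    if not sites_per_year:
        raise ValueError("no years with sites")
    m = min(len(v) for v in sites_per_year.values())
    if m < 4:
        warnings.warn(f"minimum site count per year is {m} (< 4 sites)", stacklevel=2)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 41]))
    iterations = []
    for _ in range(n_iter):
        sel = {}
        for year in sorted(sites_per_year):
            sites = sorted(sites_per_year[year])
            idx = rng.choice(len(sites), size=m, replace=False)
            sel[year] = tuple(sites[i] for i in sorted(idx))
        iterations.append(sel)
    return iterations


def occupancy_per_period(
    presences: pd.DataFrame,
    assignment: PeriodAssignment,
    site_subset: dict[int, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Per-species occupancy in the early and late periods.

    ``presences`` has one combined sample per (site_id, year): columns
    site_id, year, species_id. nsamp = (sites per year) x (years per period);
    occupancy = occupied samples / nsamp. Species absent from both periods are
    excluded.
    """
    early, late = set(assignment.early_years), set(assignment.late_years)
    frames = {}
    nsamps = {}
    for name, years in (("early", early), ("late", late)):
        sub = presences[presences["year"].isin(years)]
        if site_subset is not None:
            mask = pd.Series(False, index=sub.index)
            for y in years:
                mask |= (sub["year"] == y) & sub["site_id"].isin(site_subset.get(y, ()))
            sub = sub[mask]
            nsamp = sum(len(site_subset.get(y, ())) for y in years)
        else:
            nsamp = int(sub.drop_duplicates(["site_id", "year"]).shape[0])
        if nsamp == 0:
            raise ValueError(f"no samples in the {name} period")
        occ = (sub.drop_duplicates(["species_id", "site_id", "year"])
                  .groupby("species_id").size() / nsamp)
        frames[name] = occ
        nsamps[name] = nsamp
    table = pd.DataFrame({"occ_early": frames["early"], "occ_late": frames["late"]}).fillna(0.0)
    table = table[(table["occ_early"] > 0) | (table["occ_late"] > 0)]
    table["nsamp"] = min(nsamps["early"], nsamps["late"])
    return table.rename_axis("species_id").reset_index()


def occupancy_change(occ_early: float, occ_late: float) -> tuple[float, float]:
    """Raw and sign·sqrt-transformed occupancy change (late minus early)."""
    if not (0.0 <= occ_early <= 1.0 and 0.0 <= occ_late <= 1.0):
        raise ValueError("occupancies must lie in [0, 1]")
    delta = occ_late - occ_early
    return delta, math.copysign(math.sqrt(abs(delta)), delta)


def classify_dynamics(occ_early: float, occ_late: float) -> str:
    """Winner/loser dynamics class from period occupancies.

    lost / gained for extirpations and colonizations; persisting species are
    split by the direction of their occupancy change.
    """
    if occ_early == 0 and occ_late == 0:
        raise ValueError("species absent from both periods should not be classified")
    if occ_early > 0 and occ_late == 0:
        return "lost"
    if occ_early == 0 and occ_late > 0:
        return "gained"
    if occ_late > occ_early:
        return "persist_up"
    if occ_late < occ_early:
        return "persist_down"
    return "persist_stable"


def compute_change_table(
    presences: pd.DataFrame,
    n_iter: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Full occupancy-change table for one standardized study.

    Splits and balances periods, rarefies sites ``n_iter`` times, and returns
    one row per (iteration, species) with occupancies, raw and transformed
    change, samples per period and dynamics class.
    """
    years = sorted(presences["year"].unique())
    assignment = balance_period_years(split_periods(years))
    period_years = set(assignment.early_years) | set(assignment.late_years)
    sub = presences[presences["year"].isin(period_years)]
    sites_per_year = {
        int(y): sorted(g["site_id"].unique())
        for y, g in sub.groupby("year")
    }
    iterations = rarefy_sites(sites_per_year, n_iter=n_iter, seed=seed)
    out = []
    for it, subset in enumerate(iterations, start=1):
        table = occupancy_per_period(sub, assignment, site_subset=subset)
        deltas = table["occ_late"] - table["occ_early"]
        table["delta"] = deltas
        table["delta_transformed"] = np.sign(deltas) * np.sqrt(np.abs(deltas))
        table["dynamics"] = [classify_dynamics(e, l) for e, l in
                             zip(table["occ_early"], table["occ_late"])]
        table["iteration"] = it
        out.append(table)
    result = pd.concat(out, ignore_index=True)
    if "study_id" in presences.columns:
        result.insert(0, "study_id", presences["study_id"].iloc[0])
    return result


def dynamics_fractions(change_table: pd.DataFrame) -> pd.Series:
    """Fraction of species in each dynamics class (sums to 1)."""
    frac = change_table["dynamics"].value_counts(normalize=True)
    return frac.reindex(DYNAMICS_CLASSES, fill_value=0.0)
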