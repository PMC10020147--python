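"""Independent brute-force oracles used to cross-check the library.

These are deliberately naive reimplementations (plain dict/loop enumeration
over all year pairs) kept separate from the package code paths they verify.
"""

from __future__ import annotations

import pandas as pd


def oracle_grid_pair(df: pd.DataFrame, assignment, retained_cells, min_interval: int = 10):
    """Reference-pair choice by exhaustive enumeration (grid matching).

    Co-occurrence of a year pair = sum over cells sampled in both years of the
    smaller per-cell site count; eligible pairs exceed 90% of the maximum;
    longest duration wins, then earliest start. Returns None when no pair
    qualifies.
    """
    locs: dict[int, dict[tuple, set]] = {}
    for _, row in df.iterrows():
        cell = assignment.cell_of(row["x_km"], row["y_km"])
        if cell not in retained_cells:
            continue
        locs.setdefault(int(row["year"]), {}).setdefault(cell, set()).add(
            (round(row["x_km"], 9), round(row["y_km"], 9)))
    years = sorted(locs)
    counts = {}
    for i, a in enumerate(years):
        for b in years[i + 1:]:
            if b - a < min_interval:
                continue
            total = 0
            for cell in set(locs[a]) & set(locs[b]):
                total += min(len(locs[a][cell]), len(locs[b][cell]))
            counts[(a, b)] = total
    if not counts or max(counts.values()) == 0:
        return None
    mx = max(counts.values())
    eligible = [p for p, c in counts.items() if c > 0.9 * mx]
    return sorted(eligible, key=lambda p: (-(p[1] - p[0]), p[0]))[0]


def oracle_exact_pair(df: pd.DataFrame, min_interval: int = 10):
    """Reference-pair choice by exhaustive enumeration (exact locations)."""
    locs: dict[int, set] = {}
    for _, row in df.iterrows():
        locs.setdefault(int(row["year"]), set()).add(
            (round(row["x_km"], 9), round(row["y_km"], 9)))
    years = sorted(locs)
    counts = {}
    for i, a in enumerate(years):
        for b in years[i + 1:]:
            if b - a >= min_interval:
                counts[(a, b)] = len(locs[a] & locs[b])
    if not counts or max(counts.values()) == 0:
        return None
    mx = max(counts.values())
    eligible = [p for p, c in counts.items() if c > 0.9 * mx]
    pair = sorted(eligible, key=lambda p: (-(p[1] - p[0]), p[0]))[0]
    shared = locs[pair[0]] & locs[pair[1]]
    retained_years = sorted(y for y in years if shared <= locs[y])
    return pair, shared, retained_years


def random_toy_study(rng, max_years: int = 5, max_sites: int = 9) -> pd.DataFrame:
    """A small random survey table guaranteed to span >= 10 years."""
    n_sites = int(rng.integers(4, max_sites + 1))
    xy = rng.uniform(0.0, 50.0, size=(n_sites, 2))
    n_years = int(rng.integers(2, max_years + 1))
    years = sorted(rng.choice(range(1990, 2011), size=n_years, replace=False).tolist())
    years[0], years[-1] = 1990, 2010  # ensure an eligible pair exists
    rows = []
    for y in sorted(set(years)):
        k = int(rng.integers(2, n_sites + 1))
        for s in sorted(rng.choice(n_sites, size=k, replace=False).tolist()):
            rows.append({"study_id": "toy", "site_id": f"s{s}", "x_km": xy[s, 0],
                         "y_km": xy[s, 1], "year": y, "sample_id": "s1",
                         "species_id": "sp1"})
    return pd.DataFrame(rows)
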