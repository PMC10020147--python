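"""Site-matching and effort-equalization checks, including brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from _oracles import oracle_exact_pair, oracle_grid_pair, random_toy_study
from rangeocc.standardize import (
    DegenerateExtentError,
    StudyDroppedError,
    assign_grid_cells,
    exact_location_filter,
    exclude_sparse_years,
    filter_cells,
    filter_years_by_coverage,
    keep_modal_method,
    rarefy_sampling_effort,
    select_reference_year_pair,
    standardize_study,
)


def survey(rows, **extra):
    df = pd.DataFrame(rows, columns=["site_id", "x_km", "y_km", "year"])
    df["sample_id"] = "s1"
    df["species_id"] = "sp1"
    df["study_id"] = "t"
    for k, v in extra.items():
        df[k] = v
    return df


class TestGridAssignment:
    def test_resolution_is_fifth_of_mean_span(self):
        df = survey([("a", 0, 0, 2000), ("b", 10, 10, 2000)])
        g = assign_grid_cells(df)
        assert g.resolution == pytest.approx(2.0)
        assert g.n_cells == (5, 5)

    def test_boundary_point_falls_in_last_cell(self):
        df = survey([("a", 0, 0, 2000), ("b", 10, 10, 2000), ("c", 0.5, 0.5, 2000)])
        g = assign_grid_cells(df)
        assert g.cell_of(0.5, 0.5) == (0, 0)
        assert g.cell_of(10, 10) == (4, 4)

    def test_asymmetric_extent(self):
        df = survey([("a", 0, 0, 2000), ("b", 8, 4, 2000)])
        assert assign_grid_cells(df).resolution == pytest.approx(1.2)

    def test_degenerate_extent_raises(self):
        df = survey([("a", 1, 1, 2000), ("b", 1, 1, 2010)])
        with pytest.raises(DegenerateExtentError):
            assign_grid_cells(df)


class TestFilterCells:
    def _three_cell_toy(self):
        # cell around (0.5, 0.5): surveyed all years, one site; cells around
        # (9.5, 9.5) and (10, 0): one sparse year each; cell around (5, 5):
        # one year but 10 sites (mean sites per occupied cell = 13/4, so the
        # dense cell passes the half-mean rule and the sparse singletons fail)
        rows = [("a", 0.5, 0.5, 2000), ("a", 0.5, 0.5, 2012),
                ("z", 9.5, 9.5, 2000), ("o", 10.0, 0.0, 2000)]
        rows += [(f"m{i}", 5.0 + i * 0.01, 5.0, 2012) for i in range(10)]
        return survey(rows)

    def test_only_consistently_surveyed_or_dense_cells_kept(self):
        df = self._three_cell_toy()
        g = assign_grid_cells(df)
        kept = filter_cells(g, df)
        assert g.cell_of(0.5, 0.5) in kept          # all years
        assert g.cell_of(5.0, 5.0) in kept          # dense (4 > mean/2)
        assert g.cell_of(9.5, 9.5) not in kept      # sporadic and sparse

    def test_all_cells_kept_when_all_surveyed_every_year(self):
        rows = [(f"s{i}", x, y, yr) for i, (x, y) in enumerate([(0, 0), (5, 5), (10, 10)])
                for yr in (2000, 2012)]
        df = survey(rows)
        g = assign_grid_cells(df)
        cells = {g.cell_of(x, y) for x, y in [(0, 0), (5, 5), (10, 10)]}
        assert cells <= filter_cells(g, df)

    def test_dense_cell_missing_a_year_retained_under_union(self):
        df = self._three_cell_toy()
        g = assign_grid_cells(df)
        dense = g.cell_of(5.0, 5.0)
        years_in_dense = df[[g.cell_of(x, y) == dense
                             for x, y in zip(df.x_km, df.y_km)]]["year"].nunique()
        assert years_in_dense < df["year"].nunique()  # it does miss a year
        assert dense in filter_cells(g, df)


class TestReferencePair:
    def _df(self, years, sites=3):
        rows = [(f"s{i}", i * 3.0, i * 3.0, y) for y in years for i in range(sites)]
        return survey(rows)

    def test_longest_eligible_span_wins(self):
        df = self._df([2000, 2005, 2012])
        g = assign_grid_cells(df)
        pair = select_reference_year_pair(df, g, filter_cells(g, df))
        assert pair == (2000, 2012)

    def test_tie_broken_by_earliest_start(self):
        # 12 locations, each in its own grid cell; set A surveyed in 2000 and
        # 2012, set B in 2001 and 2013, |A & B| = 8: the cross pairs match 8
        # sites (ineligible, 8 <= 0.9 * 10) while (2000, 2012) and
        # (2001, 2013) both match 10 over a 12-year span -> earliest start
        coords = [(10 + 20 * (k % 5), 10 + 20 * (k // 5)) for k in range(12)]
        set_a, set_b = coords[:10], coords[:8] + coords[10:]
        rows = [(f"a{i}", x, y, yr) for yr in (2000, 2012)
                for i, (x, y) in enumerate(set_a)]
        rows += [(f"b{i}", x, y, yr) for yr in (2001, 2013)
                 for i, (x, y) in enumerate(set_b)]
        df = survey(rows)
        g = assign_grid_cells(df)
        pair = select_reference_year_pair(df, g, filter_cells(g, df))
        assert pair == (2000, 2012)

    def test_interval_under_ten_years_rejected(self):
        df = self._df([2000, 2005])
        g = assign_grid_cells(df)
        with pytest.raises(StudyDroppedError):
            select_reference_year_pair(df, g, filter_cells(g, df))

    def test_ninety_percent_threshold_is_strict(self):
        # pair (2000, 2012) matches 10 sites; (2000, 2013) only 8 (8 <= 9 -> ineligible)
        rows = [(f"s{i}", i * 2.0, 0.0, 2000) for i in range(10)]
        rows += [(f"s{i}", i * 2.0, 0.0, 2012) for i in range(10)]
        rows += [(f"s{i}", i * 2.0, 0.0, 2013) for i in range(8)]
        df = survey(rows)
        g = assign_grid_cells(df)
        pair = select_reference_year_pair(df, g, filter_cells(g, df))
        assert pair == (2000, 2012)


def test_year_coverage_weighting():
    # 3 selected cells with equal weight; 2005 covers 2 of them -> 2/3 <= 0.9 dropped
    rows = []
    for cell_x in (0.0, 5.0, 10.0):
        for y in (2000, 2012):
            rows.append((f"s{cell_x}", cell_x, 0.0, y))
    rows += [("s0.0", 0.0, 0.0, 2005), ("s5.0", 5.0, 0.0, 2005)]
    rows += [("s0.0", 0.0, 0.0, 2006), ("s5.0", 5.0, 0.0, 2006), ("s10.0", 10.0, 0.0, 2006)]
    df = survey(rows)
    g = assign_grid_cells(df)
    cells = filter_cells(g, df)
    pair = select_reference_year_pair(df, g, cells)
    years, _ = filter_years_by_coverage(df, g, pair, cells)
    assert 2006 in years       # covers all cells: weight 1 > 0.9
    assert 2005 not in years   # weight 2/3
    assert set(pair) <= set(years)


class TestSparseYears:
    def test_sparse_year_dropped(self):
        kept = exclude_sparse_years({2000: 10, 2006: 10, 2012: 2},
                                    reference_pair=(2000, 2012))
        assert 2006 in kept and 2000 in kept
        # 2012 is a reference year so survives; a non-reference sparse year drops
        kept2 = exclude_sparse_years({2000: 10, 2006: 2, 2012: 10},
                                     reference_pair=(2000, 2012))
        assert kept2 == (2000, 2012)

    def test_no_drop_when_counts_balanced(self):
        assert exclude_sparse_years({2000: 10, 2006: 9, 2012: 8}) == (2000, 2006, 2012)

    def test_guard_preserves_ten_year_span(self):
        with pytest.warns(UserWarning):
            kept = exclude_sparse_years({2000: 2, 2006: 10, 2008: 10})
        assert kept == (2000, 2006, 2008)


class TestEffortRarefaction:
    def test_single_sample_is_identity(self):
        df = survey([("a", 0, 0, 2000), ("b", 5, 5, 2000)])
        out = rarefy_sampling_effort(df, seed=0)
        assert len(out) == 2 and (out["sample_id"] == "combined").all()

    def test_union_keeps_species_present_in_all_samples(self):
        rows = []
        for s in ("s1", "s2", "s3"):
            rows.append({"study_id": "t", "site_id": "a", "x_km": 0, "y_km": 0,
                         "year": 2000, "sample_id": s, "species_id": "always"})
        rows.append({"study_id": "t", "site_id": "b", "x_km": 1, "y_km": 1,
                     "year": 2000, "sample_id": "s1", "species_id": "always"})
        rows.append({"study_id": "t", "site_id": "b", "x_km": 1, "y_km": 1,
                     "year": 2000, "sample_id": "s2", "species_id": "always"})
        df = pd.DataFrame(rows)
        for seed in range(5):
            out = rarefy_sampling_effort(df, seed=seed)
            assert set(out["species_id"]) == {"always"}
            assert out.groupby(["site_id", "year"]).size().eq(1).all()

    def test_seed_changes_only_partially_present_species(self):
        # site 'a' has 3 samples; species 'rare' in exactly one of them:
        # across seeds its retention varies, 'always' never drops
        rows = []
        for s in ("s1", "s2", "s3"):
            rows.append({"study_id": "t", "site_id": "a", "x_km": 0, "y_km": 0,
                         "year": 2000, "sample_id": s, "species_id": "always"})
        rows.append({"study_id": "t", "site_id": "a", "x_km": 0, "y_km": 0,
                     "year": 2000, "sample_id": "s3", "species_id": "rare"})
        rows += [{"study_id": "t", "site_id": "b", "x_km": 1, "y_km": 1,
                  "year": 2000, "sample_id": s, "species_id": "always"}
                 for s in ("s1", "s2")]
        df = pd.DataFrame(rows)
        outcomes = {tuple(sorted(rarefy_sampling_effort(df, seed=s)["species_id"].unique()))
                    for s in range(20)}
        assert ("always",) in outcomes and ("always", "rare") in outcomes


def test_modal_method_prefilter():
    df = survey([("a", 0, 0, 2000), ("b", 5, 5, 2000), ("c", 9, 9, 2000)],
                method="electrofishing")
    df.loc[df.site_id == "c", "method"] = "seining"
    out, kept = keep_modal_method(df)
    assert kept == "electrofishing"
    assert set(out["site_id"]) == {"a", "b"}


class TestExactLocation:
    def test_identical_site_sets_keep_all_years(self):
        rows = [(f"s{i}", i * 2.0, 0.0, y) for y in (2000, 2006, 2012) for i in range(5)]
        std = exact_location_filter(survey(rows))
        assert std.retained_years == (2000, 2006, 2012)
        assert len(std.retained_sites) == 5

    def test_moved_site_excluded_from_matching(self):
        rows = [(f"s{i}", i * 2.0, 0.0, 2000) for i in range(5)]
        rows += [(f"s{i}", i * 2.0, 0.0, 2012) for i in range(4)]
        rows += [("s4", 8.0, 1.0, 2012)]  # moved by 1 km
        std = exact_location_filter(survey(rows))
        assert "s4" not in std.retained_sites
        assert len(std.retained_sites) == 4


def test_pair_selection_matches_bruteforce_on_random_toys(rng):
    """Grid and exact pair selection equal exhaustive enumeration, 100 toys."""
    n_checked = 0
    for _ in range(100):
        df = random_toy_study(rng)
        g = assign_grid_cells(df)
        cells = filter_cells(g, df)
        expected = oracle_grid_pair(df, g, cells)
        if expected is None:
            with pytest.raises(StudyDroppedError):
                select_reference_year_pair(df, g, cells)
        else:
            assert select_reference_year_pair(df, g, cells) == expected
        exact = oracle_exact_pair(df)
        if exact is None:
            with pytest.raises(StudyDroppedError):
                exact_location_filter(df)
        else:
            std = exact_location_filter(df)
            assert std.reference_pair == exact[0]
            assert std.retained_years == tuple(exact[2])
        n_checked += 1
    assert n_checked == 100


def test_grid_and_exact_agree_on_constant_site_sets(small_metadataset):
    _, surveys, _ = small_metadataset
    sid = surveys["study_id"].iloc[0]
    g = surveys[surveys["study_id"] == sid].reset_index(drop=True)
    grid = standardize_study(g, mode="grid", seed=0)
    exact = standardize_study(g, mode="exact", seed=0)
    assert grid.retained_years == exact.retained_years
    assert grid.retained_sites == exact.retained_sites
    key = ["site_id", "year", "species_id"]
    pd.testing.assert_frame_equal(
        grid.data.sort_values(key, ignore_index=True)[key],
        exact.data.sort_values(key, ignore_index=True)[key])


def test_standardization_idempotent_on_constant_sites(small_metadataset):
    _, surveys, _ = small_metadataset
    sid = surveys["study_id"].iloc[1]
    g = surveys[surveys["study_id"] == sid].reset_index(drop=True)
    once = standardize_study(g, mode="grid", seed=0)
    twice = standardize_study(once.data, mode="grid", seed=0)
    key = ["site_id", "year", "species_id"]
    pd.testing.assert_frame_equal(
        once.data.sort_values(key, ignore_index=True)[key],
        twice.data.sort_values(key, ignore_index=True)[key])


def test_retained_years_span_at_least_ten(small_metadataset):
    _, surveys, _ = small_metadataset
    for _, g in surveys.groupby("study_id"):
        std = standardize_study(g.reset_index(drop=True), mode="grid", seed=0)
        assert std.retained_years[-1] - std.retained_years[0] >= 10
        assert set(std.reference_pair) <= set(std.retained_years)
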