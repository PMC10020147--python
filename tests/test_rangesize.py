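"""Occurrence cleaning, AOO, alpha-hull/buffer EOO and range covariates."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from shapely.geometry import Polygon, box

from rangeocc.rangesize import (
    alpha_hull,
    aoo,
    clean_occurrences,
    eoo_alpha_hull,
    eoo_buffer,
    estimate_ranges,
    gbif_support_filter,
    log10_center,
    study_inclusion_filter,
)


def _rec(**kw):
    base = {"record_id": 0, "species_id": "sp", "lon": 0.0, "lat": 0.0,
            "basis": "human_observation", "coord_uncertainty_km": 1.0}
    base.update(kw)
    return base


class TestCleaning:
    def test_high_uncertainty_removed(self):
        df = pd.DataFrame([_rec(record_id=1, coord_uncertainty_km=150.0),
                           _rec(record_id=2, lon=5.0)])
        out = clean_occurrences(df)
        assert list(out["record_id"]) == [2]

    def test_missing_coordinates_removed(self):
        df = pd.DataFrame([_rec(record_id=1, lon=np.nan), _rec(record_id=2, lat=np.nan),
                           _rec(record_id=3, lon=3.0)])
        assert list(clean_occurrences(df)["record_id"]) == [3]

    def test_excluded_bases_removed(self):
        df = pd.DataFrame([_rec(record_id=1, basis="fossil"),
                           _rec(record_id=2, basis="material_sample", lon=1.0),
                           _rec(record_id=3, basis="preserved_specimen", lon=2.0)])
        assert list(clean_occurrences(df)["record_id"]) == [3]

    def test_flagged_records_removed(self):
        df = pd.DataFrame([_rec(record_id=1), _rec(record_id=2, lon=1.0)])
        df["flag_centroid"] = [True, False]
        assert list(clean_occurrences(df)["record_id"]) == [2]

    def test_duplicates_within_cell_keep_first(self):
        # 0.001 degrees apart: same 0.01-degree cell -> one survives
        df = pd.DataFrame([_rec(record_id=1, lon=0.0010, lat=0.0010),
                           _rec(record_id=2, lon=0.0020, lat=0.0010),
                           _rec(record_id=3, lon=0.5000, lat=0.0010)])
        assert list(clean_occurrences(df)["record_id"]) == [1, 3]

    def test_duplicates_independent_across_species(self):
        df = pd.DataFrame([_rec(record_id=1, species_id="a"),
                           _rec(record_id=2, species_id="b")])
        assert len(clean_occurrences(df)) == 2

    def test_realm_mask_drops_outside_points(self):
        df = pd.DataFrame([_rec(record_id=1, lon=5.0, lat=5.0),
                           _rec(record_id=2, lon=50.0, lat=5.0)])
        out = clean_occurrences(df, realm_mask=box(0, 0, 10, 10))
        assert list(out["record_id"]) == [1]
        out2 = clean_occurrences(df, realm_mask=box(0, 0, 10, 10),
                                 mask_keep_inside=False)
        assert list(out2["record_id"]) == [2]

    def test_clean_records_untouched(self):
        df = pd.DataFrame([_rec(record_id=i, lon=10.0 * i) for i in range(5)])
        assert len(clean_occurrences(df)) == 5


class TestAOO:
    def test_worked_example(self):
        pts = pd.DataFrame({"lon": [1.0, 5.0, 15.0, 15.5], "lat": [1.0, 9.0, 1.0, 1.5]})
        assert aoo(pts, 10.0) == 2       # cells (0,0) and (1,0)
        assert aoo(pts, 100.0) == 1

    def test_negative_coordinates_floor_correctly(self):
        pts = pd.DataFrame({"lon": [-0.5, 0.5], "lat": [0.5, 0.5]})
        assert aoo(pts, 10.0) == 2       # cells (-1,0) and (0,0)

    def test_invalid_inputs(self):
        pts = pd.DataFrame({"lon": [1.0], "lat": [1.0]})
        with pytest.raises(ValueError):
            aoo(pts, 0.0)
        with pytest.raises(ValueError):
            aoo(pts.iloc[:0], 10.0)

    @settings(derandomize=True, max_examples=100)
    @given(arrays(float, (20, 2), elements=st.floats(-500, 500)))
    def test_coarsening_monotone(self, xy):
        pts = pd.DataFrame({"lon": xy[:, 0], "lat": xy[:, 1]})
        a10, a50, a100 = aoo(pts, 10.0), aoo(pts, 50.0), aoo(pts, 100.0)
        assert a100 <= a50 <= a10 <= len(pts)
        assert a100 >= 1


class TestAlphaHull:
    def test_large_alpha_equals_convex_hull(self, rng):
        pts = rng.uniform(0, 100, size=(40, 2))
        hull = alpha_hull(pts, alpha=1e6)
        from scipy.spatial import ConvexHull
        assert hull.area == pytest.approx(ConvexHull(pts).volume, rel=1e-9)

    def test_two_distant_clusters_split(self, rng):
        a = rng.uniform(0, 10, size=(15, 2))
        b = rng.uniform(0, 10, size=(15, 2)) + 1000.0
        hull = alpha_hull(np.vstack([a, b]), alpha=20.0)
        # each cluster's own hull, not the bridge between them
        expected = alpha_hull(a, 20.0).area + alpha_hull(b, 20.0).area
        assert hull.area == pytest.approx(expected, rel=1e-9)
        from scipy.spatial import ConvexHull
        assert hull.area < ConvexHull(np.vstack([a, b])).volume / 10

    def test_alpha_hull_never_exceeds_convex_hull(self, rng):
        from scipy.spatial import ConvexHull
        for _ in range(20):
            pts = rng.uniform(0, 50, size=(12, 2))
            assert alpha_hull(pts, 6.0).area <= ConvexHull(pts).volume + 1e-9

    def test_tiny_alpha_gives_empty_geometry(self, rng):
        pts = rng.uniform(0, 100, size=(10, 2))
        assert alpha_hull(pts, alpha=1e-6).area == 0.0

    def test_eoo_requires_four_distinct_points(self):
        pts = pd.DataFrame({"lon": [0.0, 1.0, 0.0], "lat": [0.0, 0.0, 1.0]})
        with pytest.raises(ValueError):
            eoo_alpha_hull(pts)


class TestBufferEOO:
    def test_single_point_is_disk(self):
        pts = pd.DataFrame({"lon": [0.0], "lat": [0.0]})
        assert eoo_buffer(pts, radius=10.0) == pytest.approx(math.pi * 100, rel=1e-4)

    def test_two_distant_points_two_disks(self):
        pts = pd.DataFrame({"lon": [0.0, 100.0], "lat": [0.0, 0.0]})
        assert eoo_buffer(pts, radius=10.0) == pytest.approx(2 * math.pi * 100, rel=1e-4)

    def test_coincident_points_count_once(self):
        pts = pd.DataFrame({"lon": [0.0, 0.0], "lat": [0.0, 0.0]})
        assert eoo_buffer(pts, radius=10.0) == pytest.approx(math.pi * 100, rel=1e-4)

    def test_overlapping_disks_not_double_counted(self):
        pts = pd.DataFrame({"lon": [0.0, 1.0], "lat": [0.0, 0.0]})
        area = eoo_buffer(pts, radius=10.0)
        assert math.pi * 100 < area < 2 * math.pi * 100

    def test_sum_method_double_counts(self):
        pts = pd.DataFrame({"lon": [0.0, 1.0], "lat": [0.0, 0.0]})
        assert eoo_buffer(pts, radius=10.0, method="sum") == pytest.approx(
            2 * math.pi * 100)


class TestEstimateRanges:
    def test_measure_switches_on_point_count(self):
        rows = [_rec(record_id=i, species_id="many", lon=float(10 * i),
                     lat=float(7 * (i % 3))) for i in range(8)]
        rows += [_rec(record_id=100 + i, species_id="few", lon=float(500 + 30 * i),
                      lat=0.0) for i in range(3)]
        out = estimate_ranges(pd.DataFrame(rows)).set_index("species_id")
        assert out.loc["many", "measure_used"] == "alpha_hull"
        assert out.loc["few", "measure_used"] == "buffer"
        assert (out[["aoo_10", "aoo_50", "aoo_100"]] >= 1).all().all()

    def test_collinear_points_fall_back_to_buffer(self):
        rows = [_rec(record_id=i, lon=float(20 * i), lat=0.0) for i in range(6)]
        out = estimate_ranges(pd.DataFrame(rows))
        assert out["measure_used"].iloc[0] == "buffer"
        assert out["eoo_km2"].iloc[0] > 0


class TestLog10Center:
    def test_symmetric_pair(self):
        centered, c = log10_center(pd.Series([10.0, 1000.0]))
        np.testing.assert_allclose(centered, [-1.0, 1.0])
        assert c == pytest.approx(2.0)

    def test_single_value_centers_to_zero(self):
        centered, c = log10_center([250.0])
        assert centered[0] == 0.0 and c == pytest.approx(math.log10(250.0))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log10_center([10.0, 0.0])


class TestFilters:
    def test_gbif_support_factor_five(self):
        assemblage = pd.Series({"a": 10, "b": 10, "c": 2})
        occurrences = pd.Series({"a": 100, "b": 40})  # c missing -> zero
        kept = gbif_support_filter(assemblage, occurrences)
        assert list(kept) == ["a"]

    def test_assemblage_zero_always_kept(self):
        kept = gbif_support_filter(pd.Series({"a": 0}), pd.Series(dtype=float))
        assert list(kept) == ["a"]

    def test_study_inclusion_rule(self):
        good = {1990: 6, 2005: 8, 2010: 5}
        assert study_inclusion_filter(good, 20, 15)
        assert not study_inclusion_filter({1990: 3, 2010: 8}, 20, 15)   # few sites
        assert not study_inclusion_filter(good, 8, 15)                  # short span
        assert not study_inclusion_filter(good, 20, 9)                  # few species


def test_generated_cellcounts_correlate_with_eoo(small_metadataset):
    """Synthetic occurrences: AOO target and realized EOO should co-vary."""
    from rangeocc.synth import generate_occurrences

    cfg, _, truth = small_metadataset
    sp = truth.species.drop_duplicates("species_id")
    targets = dict(zip(sp["species_id"], sp["cellcount"].astype(int)))
    occ, _ = generate_occurrences(targets, resolution=10.0, seed=21)
    est = estimate_ranges(occ, clean=False).set_index("species_id")
    merged = sp.set_index("species_id").join(est)
    # with one point per 10-km cell and alpha = 6 km, small ranges yield tied
    # near-zero hull areas, so only a moderate rank correlation is expected
    rho = merged["cellcount"].corr(merged["eoo_km2"], method="spearman")
    assert rho > 0.3
    np.testing.assert_array_equal(merged["aoo_10"], merged["cellcount"])
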