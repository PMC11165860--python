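"""Scope, quality, proximity, polygon and DBSCAN cleaning stages."""

import numpy as np
import pandas as pd
import pytest
import shapely

from phylohex import fixtures
from phylohex.cleaning import (
    DbscanSpec,
    FilterSpec,
    ReferenceGeodata,
    apply_scope,
    dbscan_outliers,
    filter_quality,
    haversine_km,
    polygon_mask,
    remove_near_points,
    run_cleaning,
)
from phylohex.occurrences import OccurrenceTable


def _table(rows):
    base = {
        "species_key": 1,
        "species_name": "Sp0001",
        "latitude": 0.0,
        "longitude": 0.0,
        "year": 2000,
        "basis_of_record": "PRESERVED_SPECIMEN",
        "coord_uncertainty_m": None,
        "coord_precision": None,
        "country_code": "AA",
        "dataset_key": "ds-a",
    }
    df = pd.DataFrame([{**base, **r} for r in rows])
    df["year"] = df["year"].astype("Int64")
    return OccurrenceTable(df)


def test_year_bounds_inclusive_both_ends():
    t = _table([{"year": y} for y in (1949, 1950, 2000, 2001)])
    out, entries = apply_scope(t, FilterSpec(min_year=1950, max_year=2000))
    assert len(out) == 2
    assert set(out.data["year"]) == {1950, 2000}


def test_missing_year_removed_only_with_active_bound():
    t = _table([{"year": None}, {"year": 1990}])
    out, _ = apply_scope(t, FilterSpec())
    assert len(out) == 2
    out, _ = apply_scope(t, FilterSpec(min_year=1950))
    assert len(out) == 1


def test_no_active_scope_is_identity():
    t = _table([{"latitude": i} for i in range(5)])
    out, entries = apply_scope(t, FilterSpec())
    assert len(out) == 5 and entries == []


def test_bbox_closed_interval_matches_brute_force():
    rng = np.random.default_rng(2)
    lons = np.round(rng.uniform(40, 60, 200), 3)
    lons[:3] = [47.0, 55.5, 47.0]  # exactly on the bounds
    t = _table([{"longitude": float(x)} for x in lons])
    spec = FilterSpec(bbox=(47.0, 55.5, -90.0, 90.0))
    out, _ = apply_scope(t, spec)
    expected = [x for x in lons if 47.0 <= x <= 55.5]
    assert sorted(out.data["longitude"]) == sorted(expected)


def test_basis_exclude_and_include():
    t = _table(
        [
            {"basis_of_record": b}
            for b in ("PRESERVED_SPECIMEN", "FOSSIL_SPECIMEN", "HUMAN_OBSERVATION")
        ]
    )
    out, _ = filter_quality(
        t, FilterSpec(basis_exclude={"FOSSIL_SPECIMEN", "HUMAN_OBSERVATION"})
    )
    assert list(out.data["basis_of_record"]) == ["PRESERVED_SPECIMEN"]

    out, _ = filter_quality(t, FilterSpec(basis_include={"PRESERVED_SPECIMEN"}))
    assert len(out) == 1

    with pytest.warns(UserWarning):
        all_obs = _table([{"basis_of_record": "HUMAN_OBSERVATION"}] * 3)
        out, _ = filter_quality(all_obs, FilterSpec(basis_include={"PRESERVED_SPECIMEN"}))
    assert len(out) == 0


def test_coord_precision_keeps_missing():
    t = _table([{"coord_precision": p} for p in (0.01, 0.1, 0.5, None)])
    out, _ = filter_quality(t, FilterSpec(max_coord_precision=0.1))
    kept = out.data["coord_precision"].tolist()
    assert len(kept) == 3 and 0.5 not in kept


def test_include_exclude_overlap_rejected():
    with pytest.raises(ValueError):
        FilterSpec(
            basis_include={"PRESERVED_SPECIMEN"}, basis_exclude={"PRESERVED_SPECIMEN"}
        ).validate()


def test_remove_near_points_haversine_radius():
    pts = pd.DataFrame({"latitude": [10.0], "longitude": [20.0]})
    t = _table(
        [
            {"latitude": 10.0, "longitude": 20.0},  # exactly at the point
            {"latitude": 11.0, "longitude": 20.0},  # 1 degree north ~ 111.19 km
        ]
    )
    assert haversine_km(10.0, 20.0, 11.0, 20.0) == pytest.approx(111.19, abs=0.05)
    out, e = remove_near_points(t, pts, radius_km=100.0)
    assert len(out) == 1 and e.rows_removed == 1
    out, _ = remove_near_points(t, pts, radius_km=120.0)
    assert len(out) == 0
    with pytest.warns(UserWarning):
        out, _ = remove_near_points(t, pd.DataFrame(columns=["latitude", "longitude"]), 10.0)
    assert len(out) == 2


def test_polygon_mask_boundary_counts_inside():
    square = shapely.box(0.0, 0.0, 1.0, 1.0)
    t = _table(
        [
            {"longitude": 0.5, "latitude": 0.5},
            {"longitude": 2.0, "latitude": 2.0},
            {"longitude": 0.0, "latitude": 0.5},  # exactly on the edge
        ]
    )
    out, _ = polygon_mask(t, [square], mode="keep_inside")
    assert len(out) == 2
    out, _ = polygon_mask(t, [square], mode="drop_inside")
    assert list(out.data["longitude"]) == [2.0]
    far = shapely.box(50, 50, 51, 51)
    out, e = polygon_mask(t, [far], mode="drop_inside")
    assert len(out) == 3 and e.rows_removed == 0
    with pytest.raises(ValueError, match="index 0"):
        bowtie = shapely.Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        polygon_mask(t, [bowtie], mode="keep_inside")


def test_dbscan_removes_distant_record():
    rng = np.random.default_rng(0)
    rows = [
        {"latitude": float(10 + rng.normal(0, 0.05)), "longitude": float(20 + rng.normal(0, 0.05))}
        for _ in range(25)
    ]
    rows.append({"latitude": 10.0, "longitude": 38.0})  # ~2000 km east
    t = _table(rows)
    out, flags, e = dbscan_outliers(t, eps_km=500.0, min_pts=20)
    assert len(out) == 25 and e.rows_removed == 1
    assert not (out.data["longitude"] > 30).any()


def test_dbscan_min_pts_one_removes_nothing():
    t = _table([{"longitude": float(x)} for x in (0, 50, 100)])
    out, _, _ = dbscan_outliers(t, eps_km=10.0, min_pts=1)
    assert len(out) == 3


def test_dbscan_sparse_species_exempt():
    t = _table([{"longitude": 0.0}, {"longitude": 100.0}])  # 2 records < min_pts
    out, _, _ = dbscan_outliers(t, eps_km=50.0, min_pts=3)
    assert len(out) == 2


def test_run_cleaning_disabled_reports_every_stage():
    t = _table([{"latitude": float(i)} for i in range(4)])
    out, report = run_cleaning(t, FilterSpec())
    assert len(out) == 4
    stages = [s.stage for s in report.stages]
    for name in ("scope", "quality", "centroids", "institutions", "land_mask", "urban_mask", "dbscan"):
        assert name in stages
    assert all(s.rows_removed == 0 for s in report.stages)


def test_run_cleaning_attributes_contamination_to_stages():
    table, manifest = fixtures.gen_occurrences(
        n_species=10,
        records_per_species=25,
        seed=3,
        centroid_dupes=6,
        planted_outliers=4,
        outlier_distance_km=2500.0,
    )
    geo = ReferenceGeodata(centroid_points=table.centroid_points)
    spec = FilterSpec(
        centroid_radius_km=2.0, dbscan=DbscanSpec(enabled=True, eps_km=500.0, min_pts=20)
    )
    out, report = run_cleaning(table, spec, geo)
    by_stage = {s.stage: s.rows_removed for s in report.stages}
    assert by_stage["centroids"] == 6
    assert by_stage["dbscan"] == 4
    assert report.rows_final == len(out)
    assert len(out) + report.total_removed() == len(table)


def test_stage_order_quality_before_dbscan():
    """A planted outlier that is also a fossil is removed at the quality stage."""
    rng = np.random.default_rng(1)
    rows = [
        {"latitude": float(rng.normal(0, 0.1)), "longitude": float(rng.normal(0, 0.1))}
        for _ in range(25)
    ]
    rows.append(
        {"latitude": 0.0, "longitude": 40.0, "basis_of_record": "FOSSIL_SPECIMEN"}
    )
    t = _table(rows)
    spec = FilterSpec(
        basis_exclude={"FOSSIL_SPECIMEN"},
        dbscan=DbscanSpec(enabled=True, eps_km=500.0, min_pts=20),
    )
    out, report = run_cleaning(t, spec)
    by_stage = {s.stage: s.rows_removed for s in report.stages}
    assert by_stage["quality_basis_exclude"] == 1
    assert by_stage["dbscan"] == 0


def test_stages_idempotent_and_permutation_invariant():
    table, _ = fixtures.gen_occurrences(
        n_species=8, records_per_species=25, seed=9, planted_outliers=3
    )
    spec = FilterSpec(
        min_year=1960, dbscan=DbscanSpec(enabled=True, eps_km=500.0, min_pts=20)
    )
    once, _ = run_cleaning(table, spec)
    twice, _ = run_cleaning(once, spec)
    assert len(once) == len(twice)

    perm = np.random.default_rng(4).permutation(len(table))
    shuffled = OccurrenceTable(table.data.iloc[perm])
    out_s, _ = run_cleaning(shuffled, spec)
    key = ["species_key", "latitude", "longitude", "year"]
    a = once.data[key].sort_values(key).reset_index(drop=True)
    b = out_s.data[key].sort_values(key).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)
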