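"""Occurrence cleaning, thinning, ranges, background sampling, extraction."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jsdmkit import prep
from jsdmkit._distance import haversine_km
from jsdmkit.tables import OccurrenceSet
from oracles import greedy_thin_reference

KM_PER_DEG_LAT = np.pi * 6371.0088 / 180.0


def occ_from(lons, lats, dates=None, species="sp"):
    n = len(lons)
    return OccurrenceSet(species, pd.DataFrame({
        "lon": lons, "lat": lats,
        "date": dates if dates is not None else ["2017-06-01"] * n,
        "source": "test"}))


class TestDeduplicate:
    def test_exact_duplicates_collapse(self):
        occ = occ_from([34.1, 34.1], [31.2, 31.2])
        assert len(prep.deduplicate(occ)) == 1

    def test_same_place_different_date_both_kept(self):
        occ = occ_from([34.1, 34.1], [31.2, 31.2],
                       dates=["2017-06-01", "2018-06-01"])
        assert len(prep.deduplicate(occ)) == 2

    def test_counts_match_row_hashing(self):
        rng = np.random.default_rng(0)
        lons = rng.uniform(34, 35, 7).round(3)
        lons = np.concatenate([lons, lons[:3]])  # 3 duplicate pairs
        lats = np.full(10, 31.5)
        dates = ["2017-01-01"] * 10
        occ = occ_from(lons, lats, dates)
        expect = len({(lo, la, d) for lo, la, d in zip(lons, lats, dates)})
        assert expect == 7
        assert len(prep.deduplicate(occ)) == 7


class TestThinning:
    def test_single_record_unchanged(self):
        occ = occ_from([34.1], [31.2])
        assert len(prep.thin_min_distance(occ, 3.0)) == 1

    def test_collinear_0_2_4_km_keeps_endpoints(self):
        """Greedy retention at 3 km keeps the 0-km and 4-km points."""
        lats = 31.0 + np.array([0.0, 2.0, 4.0]) / KM_PER_DEG_LAT
        occ = occ_from([34.5] * 3, lats)
        out = prep.thin_min_distance(occ, min_km=3.0)
        np.testing.assert_allclose(out.lat, [lats[0], lats[2]])

    def test_matches_brute_force_oracle_on_clusters(self):
        rng = np.random.default_rng(12)
        centers = rng.uniform([34, 31], [34.5, 31.5], size=(8, 2))
        pts = np.concatenate([
            c + rng.normal(scale=0.004, size=(12, 2)) for c in centers])
        occ = occ_from(pts[:, 0], pts[:, 1])
        for radius in (0.5, 1.5, 5.0):
            out = prep.thin_min_distance(occ, radius)
            kept = greedy_thin_reference(occ.lon, occ.lat, radius)
            np.testing.assert_allclose(out.lon, occ.lon[kept])
            np.testing.assert_allclose(out.lat, occ.lat[kept])

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.floats(34, 35), st.floats(31, 32)),
                    min_size=1, max_size=25), st.floats(0.1, 30))
    def test_idempotent_and_separated(self, points, radius):
        occ = occ_from([p[0] for p in points], [p[1] for p in points])
        once = prep.thin_min_distance(occ, radius)
        twice = prep.thin_min_distance(once, radius)
        pd.testing.assert_frame_equal(once.records, twice.records)
        if len(once) > 1:
            d = haversine_km(once.lon[:, None], once.lat[:, None],
                             once.lon, once.lat)
            iu = np.triu_indices(len(once), 1)
            assert np.all(d[iu] >= radius)

    def test_foraging_radius_saturates_to_one_record(self):
        occ = occ_from([34.0, 34.3, 34.6], [31.0, 31.3, 31.6])
        assert len(prep.thin_foraging_distance(occ, 500.0)) == 1

    def test_tiny_foraging_radius_keeps_all(self):
        occ = occ_from([34.0, 34.3, 34.6], [31.0, 31.3, 31.6])
        assert len(prep.thin_foraging_distance(occ, 1e-4)) == 3

    def test_missing_foraging_distance_names_species(self):
        occ = occ_from([34.0], [31.0], species="myna")
        with pytest.raises(prep.PrepError, match="myna"):
            prep.thin_foraging_distance(occ, None)


class TestSpeciesRange:
    def test_membership_radius(self):
        rng = prep.build_range(occ_from([34.5], [31.5]), home_range_km=3.0)
        near_lat = 31.5 + 2.0 / KM_PER_DEG_LAT
        far_lat = 31.5 + 4.0 / KM_PER_DEG_LAT
        assert rng.contains([34.5], [near_lat])[0]
        assert not rng.contains([34.5], [far_lat])[0]

    def test_midpoint_between_distant_records_outside(self):
        lat2 = 31.0 + 10.0 / KM_PER_DEG_LAT
        rng = prep.build_range(occ_from([34.5, 34.5], [31.0, lat2]), 3.0)
        mid = 31.0 + 5.0 / KM_PER_DEG_LAT
        assert not rng.contains([34.5], [mid])[0]

    def test_record_itself_always_inside(self):
        occ = occ_from([34.5, 34.9], [31.5, 31.1])
        rng = prep.build_range(occ, 1.0)
        assert rng.contains(occ.lon, occ.lat).all()

    def test_empty_range_is_valid_and_contains_nothing(self):
        empty = occ_from([], [])
        rng = prep.build_range(empty, 3.0)
        assert not rng.contains([34.5], [31.5]).any()


class TestBackgroundSampling:
    def test_zero_request_gives_empty(self, small_grid):
        focal = prep.build_range(occ_from([34.08], [31.08]), 2.0)
        assert len(prep.sample_background(small_grid, focal, n=0)) == 0

    def test_all_points_outside_range_by_membership_oracle(self, small_grid):
        focal = prep.build_range(occ_from([34.08, 34.02], [31.08, 31.12]),
                                 3.0)
        bg = prep.sample_background(small_grid, focal, n=200, seed=3)
        lon, lat = bg["lon"].to_numpy(), bg["lat"].to_numpy()
        d = haversine_km(lon[:, None], lat[:, None],
                         focal.centers[None, :, 0], focal.centers[None, :, 1])
        assert np.all(d.min(axis=1) > 3.0)

    def test_points_are_distinct_cells(self, small_grid):
        focal = prep.build_range(occ_from([34.08], [31.08]), 1.0)
        bg = prep.sample_background(small_grid, focal, n=500, seed=4)
        assert len(bg[["row", "col"]].drop_duplicates()) == 500

    def test_infeasible_request_reports_maximum(self, small_grid):
        focal = prep.build_range(occ_from([34.08], [31.08]), 1.0)
        with pytest.raises(prep.PrepError, match=r"\d+ valid"):
            prep.sample_background(small_grid, focal, n=10_000_000)


class TestLabelInteractors:
    def test_toy_layout_matches_brute_force(self, small_grid):
        sites = pd.DataFrame({
            "lon": [34.01, 34.05, 34.08, 34.12, 34.15],
            "lat": [31.01, 31.05, 31.08, 31.12, 31.15]})
        ranges = {
            "i1": prep.build_range(occ_from([34.05], [31.05]), 3.0),
            "i2": prep.build_range(occ_from([34.12, 34.15],
                                            [31.12, 31.15]), 2.0)}
        labels = prep.label_interactors(sites, ranges)
        for j, (name, rng) in enumerate(ranges.items()):
            for i in range(len(sites)):
                d = haversine_km(sites["lon"][i], sites["lat"][i],
                                 rng.centers[:, 0], rng.centers[:, 1])
                assert labels.iloc[i, j] == int((d <= rng.radius_km).any())

    def test_empty_range_gives_zero_column(self, small_grid):
        sites = small_grid.valid_cell_table().head(10)
        ranges = {"none": prep.build_range(occ_from([], []), 3.0)}
        assert prep.label_interactors(sites, ranges)["none"].sum() == 0


class TestExtractDesign:
    def test_constant_layer_unstandardized(self, small_grid):
        import jsdmkit.landscape as lsc
        cfg = lsc.LandscapeConfig(
            extent=(34.0, 31.0, 34.1, 31.1), cell_size=0.004, seed=1,
            predictors=[lsc.PredictorSpecification("c", 5, mean=2.5, sd=0)])
        grid = lsc.generate_predictor_grid(cfg)
        sites = grid.valid_cell_table().head(20)
        _, X, const = prep.extract_design(grid, sites, standardize=False)
        assert const is None
        assert np.all(X["c"] == 2.5)

    def test_standardization_contract_and_roundtrip(self, small_grid):
        sites = small_grid.valid_cell_table().sample(100, random_state=1)
        kept, X, const = prep.extract_design(small_grid, sites,
                                             standardize=True)
        for col in X.columns:
            assert abs(X[col].mean()) < 1e-12
            assert abs(X[col].std(ddof=0) - 1) < 1e-12
        raw = small_grid.values_at(kept["lon"], kept["lat"])
        for col in X.columns:
            mu, sd = const[col]
            np.testing.assert_allclose(X[col] * sd + mu, raw[col],
                                       atol=1e-12)

    def test_nearest_cell_agrees_with_argmin_oracle(self, small_grid):
        rng = np.random.default_rng(2)
        lons = rng.uniform(small_grid.west + 1e-6, small_grid.east - 1e-6, 50)
        lats = rng.uniform(small_grid.south + 1e-6, small_grid.north - 1e-6,
                           50)
        X = small_grid.values_at(lons, lats)
        clons, clats = small_grid.cell_centers()
        for i in range(50):
            ci = np.argmin(np.abs(clats - lats[i]))
            cj = np.argmin(np.abs(clons - lons[i]))
            for name in small_grid.names:
                assert X[name][i] == small_grid.data[name][ci, cj]

    def test_all_masked_sites_error(self, small_grid):
        import copy
        grid = copy.deepcopy(small_grid)
        grid.mask[:] = False
        sites = pd.DataFrame({"lon": [34.05], "lat": [31.05]})
        with pytest.raises(prep.PrepError):
            prep.extract_design(grid, sites)


class TestFilterByDate:
    def _mixed(self):
        dates = ["1997-05-01", "2005-01-01", "2016-03-03", "2017-12-31",
                 "2018-06-15", "2018-12-31", "1999-01-01"]
        return occ_from(np.linspace(34, 35, 7), np.full(7, 31.5), dates)

    def test_window_covering_everything_is_identity(self):
        occ = self._mixed()
        out = prep.filter_by_date(occ, "1990-01-01", "2020-01-01")
        pd.testing.assert_frame_equal(out.records, occ.records)

    def test_window_before_all_records_is_empty(self):
        assert len(prep.filter_by_date(self._mixed(), "1980-01-01",
                                       "1990-01-01")) == 0

    def test_count_matches_direct_comparison(self):
        out = prep.filter_by_date(self._mixed(), "2016-01-01", "2018-12-31")
        assert len(out) == 4  # 2016-03-03 .. 2018-12-31 inclusive

    def test_unparseable_date_logged_not_fatal(self, caplog):
        occ = occ_from([34.1, 34.2], [31.1, 31.2],
                       dates=["not-a-date", "2017-01-01"])
        with caplog.at_level(logging.WARNING):
            out = prep.filter_by_date(occ, "2016-01-01", "2018-12-31")
        assert len(out) == 1
        assert "unparseable" in caplog.text


def test_prepare_sites_end_to_end(small_grid, community_truth,
                                  simulated_sites):
    from jsdmkit import landscape as lsc
    occ = lsc.sample_presence_only(simulated_sites, community_truth, seed=31)
    # home ranges small relative to the 18-km toy grid so that enough
    # background cells remain outside the focal range
    sites = prep.prepare_sites(
        small_grid, occ, focal="focal",
        foraging_km={s: 0.3 for s in community_truth.species},
        home_range_km={s: 0.5 for s in community_truth.species},
        min_km=0.3, background_n=300, seed=1,
        date_window=("2016-01-01", "2018-12-31"))
    assert sites.focal == "focal"
    assert set(sites.species) == set(community_truth.species)
    focal_y = sites.Y["focal"].to_numpy()
    assert np.array_equal(focal_y == 1, sites.role == "focal-presence")
    assert sites.meta["n_background"] == 300
    counts = sites.meta["stage_counts"]["focal"]
    assert counts["raw"] >= counts["dedup"] >= counts["foraging_thin"] \
        >= counts["min_distance_thin"]
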