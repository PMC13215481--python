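"""Drifter-to-connectivity estimators against hand-built and brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_track
from thalassochory.connectivity import (Region, SearchAreaParams,
                                        build_search_areas,
                                        detect_island_visits,
                                        dispersal_probability_matrix,
                                        filter_low_coverage, final_search_area,
                                        initial_area_stats,
                                        minimum_dispersal_time,
                                        read_drifter_records, transit_days)
from thalassochory.geo import KM_PER_DEG, haversine_km
from thalassochory.synthetic import FlowFieldSpec, simulate_drifter_tracks

REGION = Region(10.0, 20.0, -80.0, -60.0)


class TestReader:
    def _write(self, tmp_path, frames):
        path = tmp_path / "drifters.csv"
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        return path

    def test_in_region_buoy_fully_retained(self, tmp_path):
        t = make_track("b1", "2001-01-01", [15, 15, 15], [-70, -70.1, -70.2])
        df = read_drifter_records(self._write(tmp_path, [t]), REGION)
        assert len(df) == 3

    def test_out_of_region_fixes_dropped(self, tmp_path):
        t = make_track("b1", "2001-01-01", [15, 15, 25], [-70, -70.1, -70.2])
        df = read_drifter_records(self._write(tmp_path, [t]), REGION)
        assert len(df) == 2

    def test_three_buoys_one_outside(self, tmp_path):
        inside1 = make_track("b1", "2001-01-01", [15, 15], [-70, -70.1])
        inside2 = make_track("b2", "2001-02-01", [12, 12], [-65, -65.1])
        outside = make_track("b3", "2001-03-01", [35, 35], [-70, -70.1])
        df = read_drifter_records(self._write(tmp_path, [inside1, inside2, outside]), REGION)
        assert df["id"].nunique() == 2
        assert set(df["id"]) == {"b1", "b2"}

    def test_malformed_rows_skipped(self, tmp_path):
        path = tmp_path / "messy.csv"
        path.write_text("id,datetime,lat,lon,ve,vn\n"
                        "b1,2001-01-01T00:00:00,15,-70,0.1,0\n"
                        "b1,not-a-date,15,-70.1,0.1,0\n"
                        "b1,2001-01-01T12:00:00,oops,-70.2,0.1,0\n"
                        "b1,2001-01-01T18:00:00,15,-70.3,0.1,0\n")
        df = read_drifter_records(path, REGION)
        assert len(df) == 2

    def test_empty_result_is_error(self, tmp_path):
        t = make_track("b1", "2001-01-01", [35, 35], [-70, -70.1])
        with pytest.raises(ValueError):
            read_drifter_records(self._write(tmp_path, [t]), REGION)

    def test_cm_per_s_velocities_converted(self, tmp_path):
        t = make_track("b1", "2001-01-01", [15, 15], [-70, -70.1], ve=50.0)
        df = read_drifter_records(self._write(tmp_path, [t]), REGION,
                                  velocity_unit="cm/s")
        assert np.allclose(df["ve"], 0.5)


class TestInitialAreaStats:
    def test_single_eastward_crossing(self):
        # 2 days of fixes inside a big radius, constant 0.5 m/s east
        lons = -70.0 + np.arange(9) * 0.1
        t = make_track("b1", "2001-01-01", [15.0] * 9, lons, ve=0.5, vn=0.0,
                       step_hours=6)
        stats = initial_area_stats(t, 15.0, -69.6, initial_radius_deg=2.0)
        assert stats["mean_u_e"] == pytest.approx(0.5)
        assert stats["mean_u_n"] == pytest.approx(0.0)
        assert stats["mean_retention_days"] == pytest.approx(2.0)

    def test_mean_retention_averages_over_buoys(self):
        # buoy a: 1 day in area (5 fixes), buoy b: 3 days (13 fixes)
        a = make_track("a", "2001-01-01", [15.0] * 7, [-70.0, -69.9] + [-69.5] * 4 + [-80.0])
        a.loc[2:5, "lon"] = [-69.5, -69.45, -69.4, -69.35]
        a = make_track("a", "2001-01-01", [15.0] * 5, np.linspace(-69.5, -69.1, 5))
        b = make_track("b", "2001-01-05", [15.0] * 13, np.linspace(-69.5, -69.1, 13))
        traj = pd.concat([a, b], ignore_index=True)
        stats = initial_area_stats(traj, 15.0, -69.3, initial_radius_deg=0.5)
        assert stats["mean_retention_days"] == pytest.approx(2.0)

    def test_uncovered_point_flagged(self):
        t = make_track("b1", "2001-01-01", [15, 15], [-70, -70.1])
        stats = initial_area_stats(t, 12.0, -65.0, initial_radius_deg=0.5)
        assert not stats["covered"]
        assert stats["n_buoys"] == 0

    def test_mean_flow_recovered_from_simulated_buoys(self):
        """<u> over in-area fixes lands within 3 SE of the generative mean."""
        spec = FlowFieldSpec(mean_u=0.3, mean_v=-0.1, eddy_sigma=0.15,
                             decorrelation_time=24.0,
                             lat_min=0.0, lat_max=30.0, lon_min=-90.0, lon_max=-50.0)
        starts = np.column_stack([np.full(20, 15.0), np.full(20, -70.5)])
        tracks = simulate_drifter_tracks(spec, 20, seed=5, max_fixes=60,
                                         start_points=starts)
        stats = initial_area_stats(tracks, 15.0, -70.0, initial_radius_deg=1.0)
        sub = tracks[(np.hypot((tracks["lon"] + 70.0) * np.cos(np.radians(15.0)),
                               tracks["lat"] - 15.0)) <= 1.0]
        se_u = sub["ve"].std() / math.sqrt(tracks["id"].nunique())
        assert abs(stats["mean_u_e"] - 0.3) < 3 * se_u


class TestFinalSearchArea:
    def test_lx_from_unit_conversion(self):
        stats = {"mean_u_e": 0.5, "mean_u_n": 0.0, "mean_retention_days": 2.0,
                 "n_buoys": 5, "covered": True}
        area = final_search_area("I", 0.0, -70.0, stats, initial_radius_deg=0.5)
        assert area.lx_km == pytest.approx(86.4)  # 0.5 m/s * 172800 s

    def test_zero_mean_flow_floors_at_initial_radius(self):
        stats = {"mean_u_e": 0.0, "mean_u_n": 0.0, "mean_retention_days": 2.0,
                 "n_buoys": 5, "covered": True}
        area = final_search_area("I", 15.0, -70.0, stats, initial_radius_deg=0.5)
        assert area.lx_km == pytest.approx(0.5 * KM_PER_DEG * math.cos(math.radians(15.0)))
        assert area.ly_km == pytest.approx(0.5 * KM_PER_DEG)

    def test_weak_meridional_flow_floored(self):
        stats = {"mean_u_e": 0.0, "mean_u_n": 0.1, "mean_retention_days": 1.0,
                 "n_buoys": 5, "covered": True}
        area = final_search_area("I", 15.0, -70.0, stats, initial_radius_deg=0.5)
        # 0.1 m/s * 1 d = 8.64 km, below the ~55.6 km floor
        assert area.ly_km == pytest.approx(0.5 * KM_PER_DEG)

    def test_uncovered_flag_propagates(self):
        stats = {"mean_u_e": np.nan, "mean_u_n": np.nan,
                 "mean_retention_days": np.nan, "n_buoys": 0, "covered": False}
        area = final_search_area("I", 15.0, -70.0, stats)
        assert not area.covered


def _area(island, lat, lon, l_km=30.0):
    return SearchAreaParams(island_id=island, lat=lat, lon=lon,
                            initial_radius_deg=0.25, lx_km=l_km, ly_km=l_km,
                            covered=True)


class TestVisitsAndMatrices:
    def test_single_island_pass(self):
        t = make_track("b1", "2001-01-01", [15.0] * 5, np.linspace(-70.5, -69.5, 5))
        visits = detect_island_visits(t, [_area("A", 15.0, -70.0)])
        assert len(visits) == 1
        assert visits.iloc[0]["island_id"] == "A"

    def test_two_islands_ordered_entry_times(self):
        t = make_track("b1", "2001-01-01", [15.0] * 9, np.linspace(-70.5, -68.5, 9))
        visits = detect_island_visits(t, [_area("A", 15.0, -70.0),
                                          _area("B", 15.0, -69.0)])
        v = visits.set_index("island_id")["first_entry_time"]
        assert v["A"] < v["B"]

    def test_hand_enumerated_five_buoy_three_island_fixture(self):
        """Visit table matches manual enumeration on a 5-buoy, 3-island layout."""
        areas = [_area("A", 15.0, -70.0), _area("B", 15.0, -69.0),
                 _area("C", 16.0, -69.0)]
        tracks = [
            # b1 passes A then B
            make_track("b1", "2001-01-01", [15.0] * 9, np.linspace(-70.3, -68.7, 9)),
            # b2 passes only C
            make_track("b2", "2001-01-05", [16.0] * 3, [-69.1, -69.0, -68.9]),
            # b3 passes B then A (eastward ordering reversed)
            make_track("b3", "2001-02-01", [15.0] * 9, np.linspace(-68.7, -70.3, 9)),
            # b4 misses everything
            make_track("b4", "2001-03-01", [12.0] * 3, [-75.0, -74.9, -74.8]),
            # b5 passes A only
            make_track("b5", "2001-04-01", [15.0] * 3, [-70.1, -70.0, -69.9]),
        ]
        visits = detect_island_visits(pd.concat(tracks, ignore_index=True), areas)
        got = {(r["buoy_id"], r["island_id"]) for _, r in visits.iterrows()}
        assert got == {("b1", "A"), ("b1", "B"), ("b2", "C"),
                       ("b3", "A"), ("b3", "B"), ("b5", "A")}

    def test_filter_boundary_at_ten_buoys(self):
        rows = ([{"buoy_id": f"x{i}", "island_id": "nine", "first_entry_time": i}
                 for i in range(9)]
                + [{"buoy_id": f"y{i}", "island_id": "ten", "first_entry_time": i}
                   for i in range(10)])
        visits = pd.DataFrame(rows)
        retained, dropped = filter_low_coverage(visits, ["nine", "ten"], min_buoys=10)
        assert retained == ["ten"] and dropped == ["nine"]

    def test_filter_known_counts(self):
        rows = []
        for island, n in (("a", 12), ("b", 9), ("c", 3)):
            rows += [{"buoy_id": f"{island}{i}", "island_id": island,
                      "first_entry_time": i} for i in range(n)]
        retained, dropped = filter_low_coverage(pd.DataFrame(rows), ["a", "b", "c"])
        assert retained == ["a"] and set(dropped) == {"b", "c"}

    def test_all_islands_dropped_is_error(self):
        visits = pd.DataFrame([{"buoy_id": "b", "island_id": "a", "first_entry_time": 0}])
        with pytest.raises(ValueError):
            filter_low_coverage(visits, ["a"], min_buoys=10)

    def test_quarter_probability(self):
        t0 = pd.Timestamp("2001-01-01")
        rows = [{"buoy_id": f"b{i}", "island_id": "src", "first_entry_time": t0}
                for i in range(4)]
        rows.append({"buoy_id": "b0", "island_id": "dst",
                     "first_entry_time": t0 + pd.Timedelta(days=3)})
        summary = dispersal_probability_matrix(pd.DataFrame(rows), ["src", "dst"])
        assert summary.probability.loc["src", "dst"] == pytest.approx(0.25)
        assert summary.transit_times[("src", "dst")] == [3]

    def test_reverse_order_visit_excluded(self):
        t0 = pd.Timestamp("2001-01-01")
        rows = [{"buoy_id": "b0", "island_id": "j", "first_entry_time": t0},
                {"buoy_id": "b0", "island_id": "i",
                 "first_entry_time": t0 + pd.Timedelta(days=2)}]
        summary = dispersal_probability_matrix(pd.DataFrame(rows), ["i", "j"])
        assert summary.probability.loc["i", "j"] == 0.0
        assert summary.probability.loc["j", "i"] == pytest.approx(1.0)

    def test_six_buoy_fixture_matches_brute_force(self, rng):
        """Asymmetric probability matrix equals an independent brute-force count."""
        t0 = pd.Timestamp("2001-01-01")
        islands = ["A", "B", "C"]
        entries = {}
        rows = []
        for b in range(6):
            for isl in islands:
                if rng.random() < 0.7:
                    t = t0 + pd.Timedelta(hours=int(rng.integers(0, 24 * 200)))
                    entries[(f"b{b}", isl)] = t
                    rows.append({"buoy_id": f"b{b}", "island_id": isl,
                                 "first_entry_time": t})
        summary = dispersal_probability_matrix(pd.DataFrame(rows), islands)
        for i in islands:
            visitors_i = [b for (b, isl) in entries if isl == i]
            for j in islands:
                if i == j:
                    continue
                qual = [b for b in visitors_i if (b, j) in entries
                        and entries[(b, j)] > entries[(b, i)]]
                expected = len(qual) / len(visitors_i) if visitors_i else 0.0
                assert summary.probability.loc[i, j] == pytest.approx(expected)
                expected_ts = sorted(
                    transit_days(entries[(b, j)] - entries[(b, i)]) for b in qual)
                assert summary.transit_times[(i, j)] == expected_ts

    def test_minimum_dispersal_time(self):
        mt = minimum_dispersal_time({("a", "b"): [5, 12, 88], ("b", "a"): []},
                                    ["a", "b"])
        assert mt.loc["a", "b"] == 5
        assert np.isnan(mt.loc["b", "a"])


class TestFlowInvariants:
    def _westward_setup(self, sigma, n_buoys, seed):
        spec = FlowFieldSpec(mean_u=-0.5, mean_v=0.0, eddy_sigma=sigma,
                             decorrelation_time=24.0,
                             lat_min=10.0, lat_max=20.0, lon_min=-80.0, lon_max=-60.0)
        starts = np.column_stack([np.full(n_buoys, 15.0), np.full(n_buoys, -61.0)])
        tracks = simulate_drifter_tracks(spec, n_buoys, seed=seed, start_points=starts)
        points = pd.DataFrame([{"island_id": "up", "lat": 15.0, "lon": -63.0},
                               {"island_id": "down", "lat": 15.0, "lon": -70.0}])
        areas = build_search_areas(tracks, points, initial_radius_deg=0.5)
        visits = detect_island_visits(tracks, areas)
        return tracks, areas, visits

    def test_noise_free_westward_flow_is_one_way(self):
        _, _, visits = self._westward_setup(sigma=0.0, n_buoys=5, seed=3)
        summary = dispersal_probability_matrix(visits, ["up", "down"])
        assert summary.probability.loc["up", "down"] == 1.0
        assert summary.probability.loc["down", "up"] == 0.0

    def test_stochastic_probabilities_match_brute_force_track_intersection(self):
        """Estimates equal an independent per-track intersection count."""
        tracks, areas, visits = self._westward_setup(sigma=0.2, n_buoys=40, seed=13)
        summary = dispersal_probability_matrix(visits, ["up", "down"])
        # independent oracle: loop over raw tracks, test each fix against each
        # pooled area, record first in-area times
        first = {}
        for buoy, g in tracks.groupby("id"):
            for a in areas:
                hit = a.contains(g["lat"].to_numpy(), g["lon"].to_numpy())
                if hit.any():
                    t = g["datetime"].to_numpy()[np.argmax(hit)]
                    key = (buoy, a.island_id)
                    if key not in first or t < first[key]:
                        first[key] = t
        for i, j in (("up", "down"), ("down", "up")):
            vis_i = [b for (b, isl) in first if isl == i]
            qual = [b for b in vis_i if (b, j) in first and first[(b, j)] > first[(b, i)]]
            expected = len(qual) / len(vis_i) if vis_i else 0.0
            assert summary.probability.loc[i, j] == pytest.approx(expected)

    def test_min_time_respects_distance_speed_bound(self):
        tracks, _, visits = self._westward_setup(sigma=0.2, n_buoys=40, seed=13)
        summary = dispersal_probability_matrix(visits, ["up", "down"])
        mt = summary.min_time.loc["up", "down"]
        d_km = haversine_km(15.0, -63.0, 15.0, -70.0)
        vmax = float(np.hypot(tracks["ve"], tracks["vn"]).max())  # m/s
        bound_days = d_km / (vmax * 86.4)
        assert mt >= math.floor(bound_days)
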