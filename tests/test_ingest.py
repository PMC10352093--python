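import datetime as dt
import math

import numpy as np
import pytest
from shapely.geometry import LineString, Point, Polygon

from secrsearch.ingest import (
    CaptureHistory, EffortMatrix, IngestError, ParkBoundary, SightingRecord,
    TrackLog, build_capture_history, build_state_space, compute_effort,
    filter_sightings, summarize_captures,
)

D0 = dt.date(2020, 1, 1)


def square_boundary(side=10.0):
    return ParkBoundary(polygon=Polygon([(0, 0), (side, 0), (side, side), (0, side)]))


def make_record(day=D0, x=1.0, y=1.0, iid="A", sex="female",
                age="older", quality="adequate"):
    return SightingRecord(day=day, x_km=x, y_km=y, individual_id=iid, sex=sex,
                          age_class=age, id_quality=quality)


# ---------------------------------------------------------------- state space

class TestBuildStateSpace:
    def test_square_exact_tiling(self):
        # side 1.0 divides 10.0, so the tiling is exact
        space = build_state_space(square_boundary(10.0), 1.0)
        assert space.n_pixels == 100
        assert space.total_area_km2 == pytest.approx(100.0)
        # sqrt(0.5) does not divide 10, so the centroid rule trims the
        # partial rim column/row: 14 x 14 cells, area consistent by definition
        space = build_state_space(square_boundary(10.0), 0.5)
        assert space.n_pixels == 196
        assert space.total_area_km2 == pytest.approx(0.5 * 196)

    def test_total_area_definitional(self):
        space = build_state_space(square_boundary(7.3), 0.5)
        assert space.total_area_km2 == pytest.approx(0.5 * space.n_pixels)

    def test_disc_pixel_count_matches_brute_force(self):
        disc = ParkBoundary(polygon=Point(0, 0).buffer(5.0, quad_segs=256))
        space = build_state_space(disc, 0.5)
        # brute-force oracle: centroid-in-circle count on the same grid
        g = space.grid
        ix, iy = np.meshgrid(np.arange(g.nx), np.arange(g.ny))
        cx = g.x0 + (ix.ravel() + 0.5) * g.side
        cy = g.y0 + (iy.ravel() + 0.5) * g.side
        brute = int(np.sum(cx ** 2 + cy ** 2 <= 25.0))
        assert abs(space.n_pixels - brute) <= 3          # 256-gon vs circle edge
        assert abs(space.n_pixels - 157) <= 0.04 * 157

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(IngestError):
            ParkBoundary(polygon=Polygon([(0, 0), (1, 0), (2, 0)]))

    def test_bad_pixel_area(self):
        with pytest.raises(IngestError):
            build_state_space(square_boundary(), -1.0)

    def test_centroids_inside(self):
        b = square_boundary(9.7)
        space = build_state_space(b, 0.5)
        for x, y in space.centroids:
            assert b.polygon.buffer(1e-6).contains(Point(x, y))

    def test_pixel_ids_unique(self):
        space = build_state_space(square_boundary(8.0), 0.5)
        assert len(set(space.pixel_ids)) == space.n_pixels


# --------------------------------------------------------------------- effort

class TestComputeEffort:
    def test_single_segment_one_pixel(self):
        space = build_state_space(square_boundary(9.0), 2.25)  # side 1.5 km
        tr = TrackLog(day=D0, points=[(0.1, 0.75), (1.1, 0.75)])
        eff = compute_effort([tr], space)
        assert eff.total_km == pytest.approx(1.0, abs=1e-12)
        assert eff.n_traps == 1
        assert eff.values[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_segment_bisected_by_pixel_edge(self):
        space = build_state_space(square_boundary(9.0), 2.25)
        # vertical grid line at x = 1.5; segment symmetric about it
        tr = TrackLog(day=D0, points=[(1.0, 0.75), (2.0, 0.75)])
        eff = compute_effort([tr], space)
        assert eff.n_traps == 2
        assert sorted(eff.values[:, 0]) == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_random_track_conserves_clipped_length(self, rng):
        b = square_boundary(10.0)
        space = build_state_space(b, 0.5)
        pts = rng.uniform(-2.0, 12.0, size=(100, 2))   # wanders outside
        tr = TrackLog(day=D0, points=pts)
        eff = compute_effort([tr], space)
        oracle = b.polygon.intersection(LineString(pts)).length
        assert eff.total_km == pytest.approx(oracle, abs=1e-6)

    def test_study_window_exclusion_warns(self):
        space = build_state_space(square_boundary(), 0.5)
        t1 = TrackLog(day=D0, points=[(1, 1), (2, 1)])
        t2 = TrackLog(day=D0 + dt.timedelta(days=400), points=[(1, 1), (2, 1)])
        with pytest.warns(UserWarning):
            eff = compute_effort([t1, t2], space,
                                 study_window=(D0, D0 + dt.timedelta(days=100)))
        assert eff.n_occasions == 1

    def test_occasions_are_distinct_sorted_days(self):
        space = build_state_space(square_boundary(), 0.5)
        days = [D0 + dt.timedelta(days=d) for d in (5, 1, 3)]
        tracks = [TrackLog(day=d, points=[(1, 1), (2, 1)]) for d in days]
        eff = compute_effort(tracks, space)
        assert eff.occasion_dates == sorted(days)


# ------------------------------------------------------------------ filtering

class TestFilterSightings:
    def test_paper_scale_arithmetic(self):
        recs = ([make_record(iid=f"u{i}", quality="inadequate") for i in range(61)]
                + [make_record(iid=f"c{i}", age="cub_lt1") for i in range(15)]
                + [make_record(iid=f"k{i}") for i in range(184)])
        kept, report = filter_sightings(recs)
        assert report == {"total": 260, "dropped_unidentified": 61,
                          "dropped_underage": 15, "kept": 184}
        assert len(kept) == 184

    def test_empty(self):
        kept, report = filter_sightings([])
        assert kept == [] and report["kept"] == 0

    def test_identity_on_clean_records(self):
        recs = [make_record(iid=str(i)) for i in range(10)]
        kept, _ = filter_sightings(recs)
        assert kept == recs

    def test_idempotent_and_order_stable(self):
        recs = [make_record(iid=str(i), quality="inadequate" if i % 3 == 0 else "adequate",
                            age="cub_lt1" if i % 5 == 0 else "older")
                for i in range(30)]
        once, _ = filter_sightings(recs)
        twice, _ = filter_sightings(once)
        assert twice == once
        assert [r.individual_id for r in once] == \
               [r.individual_id for r in recs if r in once]

    def test_cub_filter_applies_after_id_filter(self):
        # an inadequate cub counts as unidentified, not underage
        recs = [make_record(quality="inadequate", age="cub_lt1")]
        _, report = filter_sightings(recs)
        assert report["dropped_unidentified"] == 1
        assert report["dropped_underage"] == 0


# ------------------------------------------------------------ capture history

def _space_and_effort(n_days=3):
    space = build_state_space(square_boundary(10.0), 0.5)
    tracks = [TrackLog(day=D0 + dt.timedelta(days=d),
                       points=[(0.1, 0.1), (9.9, 9.9)]) for d in range(n_days)]
    return space, compute_effort(tracks, space)


class TestBuildCaptureHistory:
    def test_binary_collapse(self):
        space, eff = _space_and_effort()
        recs = [make_record(x=1.06, y=1.06), make_record(x=1.06, y=1.06)]
        ch, _ = build_capture_history(recs, eff, space)
        assert ch.y.sum() == 1
        assert summarize_captures(ch)["detections"] == 1

    def test_individual_counts_by_sex(self):
        space, eff = _space_and_effort()
        recs = ([make_record(iid=f"f{i}", sex="female", x=0.5 + 0.01 * i) for i in range(17)]
                + [make_record(iid=f"m{i}", sex="male", x=3.0 + 0.01 * i) for i in range(20)])
        ch, _ = build_capture_history(recs, eff, space)
        assert ch.n_individuals == 37
        summ = summarize_captures(ch)
        assert summ["individuals_by_sex"] == {"female": 17, "male": 20}

    def test_spatial_recaptures(self):
        space, eff = _space_and_effort()
        recs = [make_record(x=1.06, y=1.06),
                make_record(x=3.2, y=3.2, day=D0 + dt.timedelta(days=1)),
                make_record(x=5.3, y=5.3, day=D0 + dt.timedelta(days=2))]
        ch, _ = build_capture_history(recs, eff, space)
        assert ch.y.sum() == 3
        assert summarize_captures(ch)["avg_spatial_recaptures"] == pytest.approx(3.0)

    def test_sighting_off_track_creates_zero_effort_trap(self):
        space, eff = _space_and_effort()
        recs = [make_record(x=9.4, y=0.6)]   # far from the diagonal track
        ch, eff2 = build_capture_history(recs, eff, space)
        assert eff2.n_traps == eff.n_traps + 1
        assert eff2.values[-1].sum() == 0.0
        assert ch.y[:, -1, :].sum() == 1

    def test_unknown_occasion_errors(self):
        space, eff = _space_and_effort()
        recs = [make_record(day=D0 + dt.timedelta(days=99))]
        with pytest.raises(IngestError, match="no sampling occasion"):
            build_capture_history(recs, eff, space)

    def test_sex_conflict_errors(self):
        space, eff = _space_and_effort()
        recs = [make_record(sex="female"), make_record(sex="male")]
        with pytest.raises(IngestError, match="conflicting sex"):
            build_capture_history(recs, eff, space)

    def test_unknown_sex_errors(self):
        space, eff = _space_and_effort()
        with pytest.raises(IngestError):
            build_capture_history([make_record(sex="unknown")], eff, space)


class TestSummarizeCaptures:
    def test_single_detection(self):
        space, eff = _space_and_effort()
        ch, _ = build_capture_history([make_record()], eff, space)
        s = summarize_captures(ch)
        assert s["avg_spatial_recaptures"] == 1.0
        assert s["recaptures"] == 0

    def test_two_individuals_average(self):
        y = np.zeros((2, 6, 1), dtype=np.int8)
        y[0, :3, 0] = 1
        y[1, :5, 0] = 1
        ch = CaptureHistory(y=y, individual_ids=["a", "b"],
                            sexes=np.array(["female", "male"]),
                            trap_ids=np.arange(6), trap_xy=np.zeros((6, 2)),
                            occasion_dates=[D0])
        assert summarize_captures(ch)["avg_spatial_recaptures"] == pytest.approx(4.0)

    def test_matches_brute_force_recount(self, rng):
        n, J, K = 9, 12, 5
        y = (rng.random((n, J, K)) < 0.15).astype(np.int8)
        y[:, 0, 0] = 1      # guarantee every individual detected
        sexes = np.where(rng.random(n) < 0.5, "female", "male")
        ch = CaptureHistory(y=y, individual_ids=[str(i) for i in range(n)],
                            sexes=sexes, trap_ids=np.arange(J),
                            trap_xy=np.zeros((J, 2)),
                            occasion_dates=[D0 + dt.timedelta(days=k) for k in range(K)])
        s = summarize_captures(ch)
        det = rec = 0
        traps_per_ind = []
        for i in range(n):
            seen = set()
            for j in range(J):
                for k in range(K):
                    if y[i, j, k]:
                        det += 1
                        seen.add(j)
            traps_per_ind.append(len(seen))
        assert s["detections"] == det
        assert s["recaptures"] == det - n
        assert s["avg_spatial_recaptures"] == pytest.approx(np.mean(traps_per_ind))


def test_effort_conservation_on_simulated_scenarios():
    from secrsearch.simulate import Scenario, simulate_scenario
    for seed in (0, 1):
        sc = Scenario(area_km2=50.0, n_days=5, km_per_day=20.0, N_true=10,
                      point_spacing_km=0.25, seed=seed)
        sim = simulate_scenario(sc)
        track_total = sum(t.length_km for t in sim["tracks"])
        assert sim["effort"].total_km == pytest.approx(track_total, abs=1e-6)


def test_geographic_inputs_share_projection(tmp_path):
    """Boundary, tracks and sightings in lon/lat project consistently."""
    import json

    from secrsearch.ingest import read_boundary, read_sightings, read_tracks

    lon0, lat0 = 27.06, -25.25
    dlat = 10.0 / 111.19                      # ~10 km in degrees latitude
    dlon = 10.0 / (111.19 * math.cos(math.radians(lat0)))
    ring = [[lon0, lat0], [lon0 + dlon, lat0], [lon0 + dlon, lat0 + dlat],
            [lon0, lat0 + dlat], [lon0, lat0]]
    bpath = tmp_path / "b.geojson"
    bpath.write_text(json.dumps({"type": "Polygon", "coordinates": [ring]}))
    b = read_boundary(bpath)
    assert b.projection is not None
    assert b.area_km2 == pytest.approx(100.0, rel=0.01)

    tpath = tmp_path / "t.csv"
    tpath.write_text("date,time,lon,lat\n"
                     f"2020-01-01,06:00:00,{lon0 + 0.2 * dlon},{lat0 + 0.5 * dlat}\n"
                     f"2020-01-01,06:10:00,{lon0 + 0.8 * dlon},{lat0 + 0.5 * dlat}\n")
    tracks = read_tracks(tpath, projection=b.projection)
    assert tracks[0].length_km == pytest.approx(6.0, rel=0.01)
    for x, y in tracks[0].points:
        assert b.polygon.buffer(1e-6).contains(Point(x, y))

    spath = tmp_path / "s.csv"
    spath.write_text("date,lon,lat,individual_id,sex,age_class,id_quality\n"
                     f"2020-01-01,{lon0 + 0.5 * dlon},{lat0 + 0.5 * dlat},"
                     "A,female,older,adequate\n")
    recs = read_sightings(spath, projection=b.projection)
    assert b.polygon.contains(Point(recs[0].x_km, recs[0].y_km))


def test_roundtrip_simulation_counts(tiny_sim):
    """Ingest rebuilt from emitted sightings reproduces the simulator's counts."""
    from secrsearch.simulate import sightings_from_history

    ch = tiny_sim["capture_history"]
    recs = sightings_from_history(ch)
    kept, report = filter_sightings(recs)
    assert report["kept"] == len(recs)
    ch2, _ = build_capture_history(kept, tiny_sim["effort"], tiny_sim["space"])
    assert summarize_captures(ch2) == summarize_captures(ch)
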