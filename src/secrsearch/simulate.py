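"""Synthetic parks, drive tracks, populations and detections.

Generates data with exactly the statistical structure the pipeline assumes:
a fenced polygon gridded into half-km^2 pixels, daily bounded-random-walk
search tracks, activity centres uniform over the state space, and Bernoulli
detections from the effort-corrected cloglog model.  Defaults follow the
reserve-scale survey the pipeline targets (~500 km^2, ~90 days, ~7000 km,
~44 individuals, basal rate 0.005, effort elasticity 0.79, sex-specific
half-normal scales 3.19 / 3.85 km).
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from secrsearch.ingest import (
    CaptureHistory, EffortMatrix, ParkBoundary, SightingRecord, StateSpace,
    TrackLog, build_state_space,
)
from secrsearch.model import DetectionParams

__all__ = [
    "Scenario", "simulate_park", "simulate_tracks", "simulate_population",
    "simulate_detections", "simulate_scenario", "write_scenario_files",
]


@dataclass
class Scenario:
    """Generating parameters for one synthetic survey."""

    area_km2: float = 500.0
    pixel_area_km2: float = 0.5
    n_days: int = 90
    km_per_day: float = 78.5
    N_true: int = 44
    prop_male_true: float = 0.53
    lambda0_true: float = 0.005
    beta_eff_true: float = 0.79
    beta_sex_true: float = 0.0
    sigma_f_true: float = 3.19
    sigma_m_true: float = 3.85
    seed: int = 0
    shape: str = "rectangle"        # or "polygon"
    point_spacing_km: float = 0.05  # ~10 s at survey speed
    start_date: _dt.date = field(default_factory=lambda: _dt.date(2020, 1, 1))

    def __post_init__(self):
        if min(self.area_km2, self.pixel_area_km2, self.n_days,
               self.km_per_day, self.N_true, self.lambda0_true,
               self.sigma_f_true, self.sigma_m_true) <= 0:
            raise ValueError("scenario parameters must be positive")
        if not 0 < self.prop_male_true < 1:
            raise ValueError("prop_male_true must lie in (0, 1)")

    def detection_params(self) -> DetectionParams:
        return DetectionParams(lambda0=self.lambda0_true,
                               beta_eff=self.beta_eff_true,
                               beta_sex=self.beta_sex_true,
                               sigma_f=self.sigma_f_true,
                               sigma_m=self.sigma_m_true)


def simulate_park(area_km2: float, seed: int = 0,
                  shape: str = "rectangle", aspect: float = 1.25) -> ParkBoundary:
    """A rectangle (default) or seeded random convex polygon of the given area."""
    if area_km2 <= 0:
        raise ValueError("area must be positive")
    rng = np.random.default_rng(seed)
    if shape == "rectangle":
        w = math.sqrt(area_km2 * aspect)
        h = area_km2 / w
        poly = Polygon([(0, 0), (w, 0), (w, h), (0, h)])
    elif shape == "polygon":
        npts = 12
        ang = np.sort(rng.uniform(0, 2 * math.pi, npts))
        rad = rng.uniform(0.7, 1.0, npts)
        pts = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
        poly = Polygon(pts).convex_hull
        poly = Polygon(np.asarray(poly.exterior.coords) * math.sqrt(area_km2 / poly.area))
    else:
        raise ValueError(f"unknown park shape {shape!r}")
    assert abs(poly.area - area_km2) <= 0.01 * area_km2
    return ParkBoundary(polygon=poly, source_crs="local_km")


def _walk_day(rng, polygon: Polygon, km: float, spacing: float) -> np.ndarray:
    """Bounded correlated random walk of total length `km` inside the polygon."""
    minx, miny, maxx, maxy = polygon.bounds
    cx, cy = polygon.centroid.x, polygon.centroid.y
    # start well inside
    for _ in range(200):
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if polygon.contains(Point(x, y)):
            break
    else:
        x, y = cx, cy
    n_steps = max(1, int(round(km / spacing)))
    heading = rng.uniform(0, 2 * math.pi)
    pts = np.empty((n_steps + 1, 2))
    pts[0] = (x, y)
    for t in range(n_steps):
        for _try in range(24):
            h = heading + 0.35 * rng.standard_normal()
            nx_, ny_ = x + spacing * math.cos(h), y + spacing * math.sin(h)
            if polygon.contains(Point(nx_, ny_)):
                heading = h
                x, y = nx_, ny_
                break
            heading = math.atan2(cy - y, cx - x) + 0.5 * rng.standard_normal()
        else:
            # forced step toward the centroid keeps the step length exact
            h = math.atan2(cy - y, cx - x)
            x, y = x + spacing * math.cos(h), y + spacing * math.sin(h)
            heading = h
        pts[t + 1] = (x, y)
    return pts


def simulate_tracks(boundary: ParkBoundary, n_days: int, km_per_day: float,
                    seed: int = 0, point_spacing_km: float = 0.05,
                    start_date: _dt.date = _dt.date(2020, 1, 1)) -> list:
    """One bounded random-walk track per day, points ~10 s apart.

    Per-day polyline length matches the request within 2% (step count
    rounding is the only source of discrepancy).
    """
    if km_per_day <= 0:
        raise ValueError("km_per_day must be positive")
    rng = np.random.default_rng(seed)
    tracks = []
    for d in range(n_days):
        pts = _walk_day(rng, boundary.polygon, km_per_day, point_spacing_km)
        ts = np.arange(len(pts)) * np.timedelta64(10, "s") + np.timedelta64(6 * 3600, "s")
        tracks.append(TrackLog(day=start_date + _dt.timedelta(days=d),
                               points=pts, timestamps=ts))
    return tracks


def simulate_population(space: StateSpace, N_true: int, prop_male: float,
                        seed: int = 0) -> tuple:
    """Uniform activity centres over state-space pixels; Bernoulli sexes.

    Returns ``(centres, sexes)`` with centres as state-space row indices and
    sexes as a 0/1 male indicator.
    """
    if not 0 <= prop_male <= 1:
        raise ValueError("prop_male must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    centres = rng.integers(0, space.n_pixels, size=N_true)
    sexes = (rng.random(N_true) < prop_male).astype(np.int8)
    return centres, sexes


def simulate_detections(params: DetectionParams, effort: EffortMatrix,
                        centres: np.ndarray, sexes: np.ndarray,
                        space: StateSpace, seed: int = 0) -> tuple:
    """Bernoulli capture tensor from the cloglog detection model.

    Individuals with no detections are dropped from the emitted
    CaptureHistory but recorded in the returned truth frame
    (``individual, sex, centre_x, centre_y, detected_flag``).
    """
    rng = np.random.default_rng(seed)
    xy = space.centroids[centres]                              # (N, 2)
    d = np.sqrt(((xy[:, None, :] - effort.trap_xy[None, :, :]) ** 2).sum(-1))
    # vectorised cloglog probabilities, (N, J, K); matches detection_prob
    male = sexes.astype(float)[:, None, None]
    sig = np.where(male == 1, params.sigma_m, params.sigma_f)
    e = effort.values[None, :, :]
    with np.errstate(divide="ignore"):
        eta = (np.log(params.lambda0)
               + params.beta_eff * np.log(np.where(e > 0, e, 1.0))
               + params.beta_sex * male
               - (d[:, :, None] ** 2) / (2.0 * sig ** 2))
    pi = np.where(e > 0, -np.expm1(-np.exp(eta)), 0.0)
    y = (rng.random(pi.shape) < pi).astype(np.int8)

    detected = y.reshape(len(centres), -1).sum(axis=1) > 0
    ids = [f"L{i + 1:03d}" for i in range(len(centres))]
    truth = pd.DataFrame({
        "individual": ids,
        "sex": np.where(sexes == 1, "male", "female"),
        "centre_x": xy[:, 0],
        "centre_y": xy[:, 1],
        "detected_flag": detected.astype(int),
    })
    if detected.any():
        ch = CaptureHistory(
            y=y[detected], individual_ids=[i for i, dflag in zip(ids, detected) if dflag],
            sexes=np.where(sexes[detected] == 1, "male", "female"),
            trap_ids=effort.trap_ids, trap_xy=effort.trap_xy,
            occasion_dates=effort.occasion_dates)
    else:
        ch = None
    return ch, truth


def sightings_from_history(ch: CaptureHistory) -> list:
    """Sighting records equivalent to a capture history (at trap centroids)."""
    recs = []
    i, j, k = np.nonzero(ch.y)
    for a, b, c in zip(i, j, k):
        recs.append(SightingRecord(
            day=ch.occasion_dates[c], x_km=float(ch.trap_xy[b, 0]),
            y_km=float(ch.trap_xy[b, 1]), individual_id=ch.individual_ids[a],
            sex=str(ch.sexes[a]), age_class="older", id_quality="adequate"))
    return recs


def simulate_scenario(sc: Scenario) -> dict:
    """End-to-end simulation: park, state space, tracks, effort, captures.

    Seeds for the sub-stages are spawned deterministically from
    ``sc.seed``.
    """
    from secrsearch.ingest import compute_effort

    ss = np.random.SeedSequence(sc.seed)
    s_park, s_trk, s_pop, s_det = [int(x.generate_state(1)[0]) for x in ss.spawn(4)]
    boundary = simulate_park(sc.area_km2, seed=s_park, shape=sc.shape)
    space = build_state_space(boundary, sc.pixel_area_km2)
    tracks = simulate_tracks(boundary, sc.n_days, sc.km_per_day, seed=s_trk,
                             point_spacing_km=sc.point_spacing_km,
                             start_date=sc.start_date)
    effort = compute_effort(tracks, space)
    centres, sexes = simulate_population(space, sc.N_true, sc.prop_male_true,
                                         seed=s_pop)
    ch, truth = simulate_detections(sc.detection_params(), effort, centres,
                                    sexes, space, seed=s_det)
    return {"boundary": boundary, "space": space, "tracks": tracks,
            "effort": effort, "capture_history": ch, "truth": truth,
            "centres": centres, "sexes": sexes}


def write_scenario_files(sim: dict, outdir, scenario: Scenario) -> dict:
    """Write boundary / tracks / sightings / truth in the ingest formats."""
    import json
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    bpath = os.path.join(outdir, "boundary.geojson")
    poly = sim["boundary"].polygon
    with open(bpath, "w") as fh:
        json.dump({"type": "Polygon",
                   "coordinates": [list(map(list, poly.exterior.coords))],
                   "crs_label": "local_km"}, fh)
    paths["boundary"] = bpath

    rows = []
    for tr in sim["tracks"]:
        secs = (np.asarray(tr.timestamps) / np.timedelta64(1, "s")).astype(int) \
            if tr.timestamps is not None else np.arange(len(tr.points)) * 10
        for (x, y), s in zip(tr.points, secs):
            rows.append((tr.day.isoformat(),
                         f"{s // 3600:02d}:{s % 3600 // 60:02d}:{s % 60:02d}",
                         x, y))
    tpath = os.path.join(outdir, "tracks.csv")
    pd.DataFrame(rows, columns=["date", "time", "lon", "lat"]).to_csv(tpath, index=False)
    paths["tracks"] = tpath

    spath = os.path.join(outdir, "sightings.csv")
    ch = sim["capture_history"]
    recs = sightings_from_history(ch) if ch is not None else []
    pd.DataFrame([{
        "date": r.day.isoformat(), "lon": r.x_km, "lat": r.y_km,
        "individual_id": r.individual_id, "sex": r.sex,
        "age_class": r.age_class, "id_quality": r.id_quality,
    } for r in recs]).to_csv(spath, index=False)
    paths["sightings"] = spath

    upath = os.path.join(outdir, "truth.csv")
    sim["truth"].to_csv(upath, index=False)
    paths["truth"] = upath

    mpath = os.path.join(outdir, "scenario.json")
    with open(mpath, "w") as fh:
        json.dump({k: (v.isoformat() if isinstance(v, _dt.date) else v)
                   for k, v in vars(scenario).items()}, fh, indent=2)
    paths["manifest"] = mpath
    return paths
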