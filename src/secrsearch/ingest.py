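"""Discretisation of raw search-encounter data into SECR inputs.

Turns a reserve boundary polygon, daily GPS drive tracks and identified
sighting records into:

* a :class:`StateSpace` of candidate activity-centre pixels (0.5 km^2 by
  default) whose centroids fall inside the boundary,
* an :class:`EffortMatrix` of kilometres driven per trap pixel per occasion
  (occasion = calendar day with at least one track),
* a binary :class:`CaptureHistory` (individuals x traps x occasions).

All geometry is handled in a planar frame measured in kilometres.  Inputs in
geographic coordinates are projected with a local equirectangular projection
(adequate at reserve scale, ~10 km extents); inputs already in a metric
frame pass through unchanged (``source_crs="local_km"``).
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, MultiLineString, Polygon, shape as _shape
from shapely import contains_xy

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "ParkBoundary", "StateSpace", "TrackLog", "SightingRecord",
    "EffortMatrix", "CaptureHistory", "Grid",
    "build_state_space", "compute_effort", "filter_sightings",
    "build_capture_history", "summarize_captures",
    "read_boundary", "read_tracks", "read_sightings",
    "write_effort_table", "write_capture_table", "write_trap_table",
]


class IngestError(ValueError):
    """Raised for invalid or inconsistent raw inputs."""


# ---------------------------------------------------------------------------
# projection

@dataclass(frozen=True)
class LocalProjection:
    """Equirectangular projection about a reference point, in km."""

    lon0: float
    lat0: float

    def forward(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        kx = EARTH_RADIUS_KM * math.cos(math.radians(self.lat0)) * math.pi / 180.0
        ky = EARTH_RADIUS_KM * math.pi / 180.0
        return (lon - self.lon0) * kx, (lat - self.lat0) * ky


# ---------------------------------------------------------------------------
# domain types

@dataclass
class ParkBoundary:
    """Closed reserve boundary in a planar km frame.

    When built from geographic coordinates, ``projection`` records the local
    projection used, so tracks and sightings can be projected consistently.
    """

    polygon: Polygon
    source_crs: str = "local_km"
    projection: LocalProjection | None = None

    def __post_init__(self):
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise IngestError("boundary polygon is degenerate (invalid or zero area)")

    @property
    def area_km2(self) -> float:
        return self.polygon.area


@dataclass(frozen=True)
class Grid:
    """Regular square grid anchored at the lower-left of a bounding box."""

    x0: float
    y0: float
    side: float
    nx: int
    ny: int

    def cell_of(self, x, y):
        """Linear cell index for planar coordinates (clipped to grid range)."""
        ix = np.clip(np.floor((np.asarray(x) - self.x0) / self.side).astype(int), 0, self.nx - 1)
        iy = np.clip(np.floor((np.asarray(y) - self.y0) / self.side).astype(int), 0, self.ny - 1)
        return iy * self.nx + ix

    def centroid(self, cell_id):
        cell_id = np.asarray(cell_id)
        ix = cell_id % self.nx
        iy = cell_id // self.nx
        return (self.x0 + (ix + 0.5) * self.side, self.y0 + (iy + 0.5) * self.side)


@dataclass
class StateSpace:
    """Candidate activity-centre pixels covering the reserve interior."""

    grid: Grid
    pixel_ids: np.ndarray          # linear grid ids, centroid inside boundary
    centroids: np.ndarray          # (P, 2) km
    pixel_area_km2: float
    boundary: ParkBoundary | None = None

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_ids)

    @property
    def total_area_km2(self) -> float:
        return self.n_pixels * self.pixel_area_km2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pixel_id": self.pixel_ids,
            "x_km": self.centroids[:, 0],
            "y_km": self.centroids[:, 1],
        })


@dataclass
class TrackLog:
    """One day's drive track: ordered timestamped points in km."""

    day: _dt.date
    points: np.ndarray             # (n, 2) km
    timestamps: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 1:
            raise IngestError(f"track for {self.day} needs at least one point")
        if self.timestamps is not None:
            ts = np.asarray(self.timestamps)
            if len(ts) != len(self.points):
                raise IngestError("timestamps/points length mismatch")
            if len(ts) > 1 and not np.all(ts[1:] > ts[:-1]):
                raise IngestError(f"timestamps not strictly increasing on {self.day}")

    @property
    def length_km(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.sum(np.hypot(*np.diff(self.points, axis=0).T)))


FEMALE, MALE = "female", "male"


@dataclass
class SightingRecord:
    day: _dt.date
    x_km: float
    y_km: float
    individual_id: str
    sex: str = "unknown"
    age_class: str = "older"       # {"cub_lt1", "older"}
    id_quality: str = "adequate"   # {"adequate", "inadequate"}


@dataclass
class EffortMatrix:
    """Kilometres driven per trap pixel (J) per occasion (K)."""

    values: np.ndarray             # (J, K) km
    trap_ids: np.ndarray           # linear grid ids
    trap_xy: np.ndarray            # (J, 2) centroids km
    occasion_dates: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise IngestError("negative effort")

    @property
    def n_traps(self) -> int:
        return self.values.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.values.shape[1]

    @property
    def total_km(self) -> float:
        return float(self.values.sum())

    def occasion_index(self) -> dict:
        return {d: k for k, d in enumerate(self.occasion_dates)}

    def trap_index(self) -> dict:
        return {int(t): j for j, t in enumerate(self.trap_ids)}


@dataclass
class CaptureHistory:
    """Binary detections: n individuals x J traps x K occasions."""

    y: np.ndarray                  # (n, J, K) in {0, 1}
    individual_ids: list
    sexes: np.ndarray              # (n,) "female"/"male"
    trap_ids: np.ndarray
    trap_xy: np.ndarray
    occasion_dates: list

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.int8)
        if not np.isin(self.y, (0, 1)).all():
            raise IngestError("capture history entries must be binary")
        if self.y.shape[0] and self.y.reshape(self.y.shape[0], -1).sum(axis=1).min() < 1:
            raise IngestError("every individual must have at least one detection")

    @property
    def n_individuals(self) -> int:
        return self.y.shape[0]


# ---------------------------------------------------------------------------
# operations

def build_state_space(boundary: ParkBoundary, pixel_area_km2: float = 0.5) -> StateSpace:
    """Grid the boundary's bounding box into square pixels of the given area.

    A pixel is retained iff its centroid falls inside (or on) the polygon.
    The grid origin is the bounding-box lower-left corner, so the result is
    deterministic for a given boundary.
    """
    if pixel_area_km2 <= 0:
        raise IngestError("pixel_area_km2 must be positive")
    side = math.sqrt(pixel_area_km2)
    minx, miny, maxx, maxy = boundary.polygon.bounds
    nx = max(1, int(math.ceil((maxx - minx) / side - 1e-9)))
    ny = max(1, int(math.ceil((maxy - miny) / side - 1e-9)))
    grid = Grid(minx, miny, side, nx, ny)
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny))
    cx = minx + (ix.ravel() + 0.5) * side
    cy = miny + (iy.ravel() + 0.5) * side
    # tiny buffer so centroids exactly on the boundary count as inside
    inside = contains_xy(boundary.polygon.buffer(1e-9), cx, cy)
    ids = (iy.ravel() * nx + ix.ravel())[inside]
    centroids = np.column_stack([cx[inside], cy[inside]])
    if len(ids) == 0:
        raise IngestError("no pixel centroid falls inside the boundary")
    return StateSpace(grid=grid, pixel_ids=ids, centroids=centroids,
                      pixel_area_km2=pixel_area_km2, boundary=boundary)


def _segment_cells(grid: Grid, p0, p1):
    """Split a segment at grid-line crossings; yield (cell_id, length_km)."""
    x0, y0 = p0
    x1, y1 = p1
    dx, dy = x1 - x0, y1 - y0
    seg_len = math.hypot(dx, dy)
    if seg_len == 0.0:
        return []
    ts = [0.0, 1.0]
    if dx != 0.0:
        i0 = math.floor((x0 - grid.x0) / grid.side)
        i1 = math.floor((x1 - grid.x0) / grid.side)
        for i in range(min(i0, i1) + 1, max(i0, i1) + 1):
            t = (grid.x0 + i * grid.side - x0) / dx
            if 0.0 < t < 1.0:
                ts.append(t)
    if dy != 0.0:
        j0 = math.floor((y0 - grid.y0) / grid.side)
        j1 = math.floor((y1 - grid.y0) / grid.side)
        for j in range(min(j0, j1) + 1, max(j0, j1) + 1):
            t = (grid.y0 + j * grid.side - y0) / dy
            if 0.0 < t < 1.0:
                ts.append(t)
    ts = sorted(set(ts))
    out = []
    for ta, tb in zip(ts[:-1], ts[1:]):
        tm = 0.5 * (ta + tb)
        cell = int(grid.cell_of(x0 + tm * dx, y0 + tm * dy))
        out.append((cell, (tb - ta) * seg_len))
    return out


def _clip_to_boundary(points: np.ndarray, polygon: Polygon):
    """Clip a polyline to the polygon; return list of coordinate arrays."""
    if len(points) < 2:
        return []
    line = LineString(points)
    clipped = polygon.intersection(line)
    pieces = []
    if clipped.is_empty:
        return pieces
    geoms = clipped.geoms if isinstance(clipped, MultiLineString) or clipped.geom_type == "GeometryCollection" else [clipped]
    for g in geoms:
        if g.geom_type == "LineString" and g.length > 0:
            pieces.append(np.asarray(g.coords))
    return pieces


def compute_effort(tracks: list, space: StateSpace,
                   study_window: tuple | None = None) -> EffortMatrix:
    """Apportion daily track lengths to grid pixels -> km per trap per day.

    Consecutive point pairs form segments; each segment is clipped to the
    boundary (when the state space carries one) and split exactly at
    grid-line crossings, so the matrix total equals the in-boundary polyline
    length to floating-point accuracy.  Occasions are the ordered distinct
    track days; traps are the pixels with nonzero effort on any occasion.
    """
    import warnings

    kept = []
    for tr in tracks:
        if study_window is not None and not (study_window[0] <= tr.day <= study_window[1]):
            warnings.warn(f"track day {tr.day} outside study window; excluded")
            continue
        kept.append(tr)
    if not kept:
        raise IngestError("no tracks within the study window")

    days = sorted({tr.day for tr in kept})
    day_idx = {d: k for k, d in enumerate(days)}
    grid = space.grid
    boundary = space.boundary
    acc: dict = {}
    for tr in kept:
        k = day_idx[tr.day]
        if boundary is not None:
            pieces = _clip_to_boundary(tr.points, boundary.polygon)
        else:
            pieces = [tr.points] if len(tr.points) >= 2 else []
        for pts in pieces:
            for a, b in zip(pts[:-1], pts[1:]):
                for cell, length in _segment_cells(grid, a, b):
                    acc[(cell, k)] = acc.get((cell, k), 0.0) + length

    trap_ids = np.array(sorted({c for c, _ in acc}), dtype=int)
    tix = {int(t): j for j, t in enumerate(trap_ids)}
    values = np.zeros((len(trap_ids), len(days)))
    for (cell, k), length in acc.items():
        values[tix[cell], k] += length
    cx, cy = grid.centroid(trap_ids)
    return EffortMatrix(values=values, trap_ids=trap_ids,
                        trap_xy=np.column_stack([cx, cy]), occasion_dates=days)


def filter_sightings(records: list) -> tuple:
    """Drop unidentifiable records, then records of individuals under 1 year.

    Returns ``(kept, report)`` where report counts
    ``total / dropped_unidentified / dropped_underage / kept``.
    """
    total = len(records)
    identified = [r for r in records if r.id_quality != "inadequate"]
    kept = [r for r in identified if r.age_class != "cub_lt1"]
    report = {
        "total": total,
        "dropped_unidentified": total - len(identified),
        "dropped_underage": len(identified) - len(kept),
        "kept": len(kept),
    }
    return kept, report


def build_capture_history(kept: list, effort: EffortMatrix,
                          space: StateSpace) -> tuple:
    """Binary-collapse sightings into an n x J x K capture tensor.

    Sightings that fall in pixels with no driven effort are accommodated by
    appending zero-effort trap rows (opportunistic detections must remain
    representable); the returned effort matrix is the aligned, possibly
    extended one.

    Returns ``(CaptureHistory, EffortMatrix)``.
    """
    occ_idx = effort.occasion_index()
    bad = [r for r in kept if r.day not in occ_idx]
    if bad:
        days = sorted({r.day for r in bad})
        raise IngestError(f"sightings on days with no sampling occasion: {days}")
    for r in kept:
        if r.individual_id in ("", "UNKNOWN") or r.sex not in (FEMALE, MALE):
            raise IngestError(f"record {r} lacks a known individual_id/sex")

    grid = space.grid
    trap_ids = list(int(t) for t in effort.trap_ids)
    tix = {t: j for j, t in enumerate(trap_ids)}
    extra = []
    for r in kept:
        cell = int(grid.cell_of(r.x_km, r.y_km))
        if cell not in tix:
            tix[cell] = len(trap_ids)
            trap_ids.append(cell)
            extra.append(cell)

    J = len(trap_ids)
    K = effort.n_occasions
    values = np.zeros((J, K))
    values[: effort.n_traps] = effort.values
    cx, cy = grid.centroid(np.array(trap_ids))
    effort_ext = EffortMatrix(values=values, trap_ids=np.array(trap_ids, dtype=int),
                              trap_xy=np.column_stack([cx, cy]),
                              occasion_dates=effort.occasion_dates)

    ids, sexes = [], {}
    for r in kept:
        if r.individual_id not in sexes:
            sexes[r.individual_id] = r.sex
            ids.append(r.individual_id)
        elif sexes[r.individual_id] != r.sex:
            raise IngestError(f"conflicting sex records for {r.individual_id}")
    iix = {u: i for i, u in enumerate(ids)}

    y = np.zeros((len(ids), J, K), dtype=np.int8)
    for r in kept:
        cell = int(grid.cell_of(r.x_km, r.y_km))
        y[iix[r.individual_id], tix[cell], occ_idx[r.day]] = 1

    ch = CaptureHistory(y=y, individual_ids=ids,
                        sexes=np.array([sexes[u] for u in ids]),
                        trap_ids=effort_ext.trap_ids, trap_xy=effort_ext.trap_xy,
                        occasion_dates=effort.occasion_dates)
    return ch, effort_ext


def summarize_captures(ch: CaptureHistory) -> dict:
    """Detection totals, recaptures and average spatial recaptures.

    Average spatial recaptures = mean over individuals of the number of
    distinct trap pixels in which each was detected.
    """
    per_ind = ch.y.reshape(ch.n_individuals, -1).sum(axis=1)
    distinct_traps = (ch.y.max(axis=2) > 0).sum(axis=1)
    det = int(per_ind.sum())
    by_sex = {s: int(per_ind[ch.sexes == s].sum()) for s in (FEMALE, MALE)}
    n_by_sex = {s: int((ch.sexes == s).sum()) for s in (FEMALE, MALE)}
    return {
        "n_individuals": ch.n_individuals,
        "detections": det,
        "detections_by_sex": by_sex,
        "individuals_by_sex": n_by_sex,
        "recaptures": det - ch.n_individuals,
        "avg_spatial_recaptures": float(distinct_traps.mean()) if ch.n_individuals else 0.0,
    }


# ---------------------------------------------------------------------------
# file IO

def read_boundary(path) -> ParkBoundary:
    """Read a GeoJSON polygon; geographic coordinates are projected to km."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geom = gj["features"][0]["geometry"]
    elif gj.get("type") == "Feature":
        geom = gj["geometry"]
    else:
        geom = gj
    poly = _shape(geom)
    crs = gj.get("crs_label", gj.get("properties", {}).get("crs_label", "EPSG:4326")) \
        if isinstance(gj.get("properties"), dict) or "crs_label" in gj else "EPSG:4326"
    if crs == "local_km":
        return ParkBoundary(polygon=poly, source_crs=crs)
    lon0, lat0 = poly.centroid.x, poly.centroid.y
    proj = LocalProjection(lon0, lat0)
    xs, ys = proj.forward(*np.asarray(poly.exterior.coords).T)
    return ParkBoundary(polygon=Polygon(np.column_stack([xs, ys])),
                        source_crs=str(crs), projection=proj)


def _parse_day(s: str) -> _dt.date:
    return _dt.date.fromisoformat(str(s))


def read_tracks(path, projection: LocalProjection | None = None) -> list:
    """Read track points (header ``date,time,lon,lat``) into daily TrackLogs."""
    df = pd.read_csv(path)
    need = {"date", "time", "lon", "lat"}
    if not need.issubset(df.columns):
        raise IngestError(f"track file must have columns {sorted(need)}")
    if projection is not None:
        xs, ys = projection.forward(df["lon"].to_numpy(), df["lat"].to_numpy())
    else:
        xs, ys = df["lon"].to_numpy(float), df["lat"].to_numpy(float)
    df = df.assign(_x=xs, _y=ys)
    tracks = []
    for day, g in df.groupby("date", sort=True):
        ts = pd.to_timedelta(g["time"]).to_numpy()
        order = np.argsort(ts, kind="stable")
        g = g.iloc[order]
        tracks.append(TrackLog(day=_parse_day(day),
                               points=np.column_stack([g["_x"], g["_y"]]),
                               timestamps=ts[order]))
    return tracks


def read_sightings(path, projection: LocalProjection | None = None) -> list:
    """Read sighting records (header ``date,lon,lat,individual_id,sex,age_class,id_quality``)."""
    df = pd.read_csv(path, dtype={"individual_id": str})
    need = {"date", "lon", "lat", "individual_id", "sex", "age_class", "id_quality"}
    if not need.issubset(df.columns):
        raise IngestError(f"sightings file must have columns {sorted(need)}")
    if projection is not None:
        xs, ys = projection.forward(df["lon"].to_numpy(), df["lat"].to_numpy())
    else:
        xs, ys = df["lon"].to_numpy(float), df["lat"].to_numpy(float)
    return [
        SightingRecord(day=_parse_day(row["date"]), x_km=float(x), y_km=float(y),
                       individual_id=str(row["individual_id"]), sex=str(row["sex"]),
                       age_class=str(row["age_class"]), id_quality=str(row["id_quality"]))
        for (_, row), x, y in zip(df.iterrows(), xs, ys)
    ]


def write_effort_table(effort: EffortMatrix, path) -> None:
    j, k = np.nonzero(effort.values)
    pd.DataFrame({
        "trap_id": effort.trap_ids[j],
        "occasion_date": [effort.occasion_dates[i] for i in k],
        "effort_km": effort.values[j, k],
    }).to_csv(path, index=False)


def write_capture_table(ch: CaptureHistory, path) -> None:
    i, j, k = np.nonzero(ch.y)
    pd.DataFrame({
        "individual_id": [ch.individual_ids[a] for a in i],
        "sex": [ch.sexes[a] for a in i],
        "trap_id": ch.trap_ids[j],
        "occasion_date": [ch.occasion_dates[b] for b in k],
        "value": np.ones(len(i), dtype=int),
    }).to_csv(path, index=False)


def write_trap_table(effort: EffortMatrix, path) -> None:
    pd.DataFrame({
        "trap_id": effort.trap_ids,
        "x_km": effort.trap_xy[:, 0],
        "y_km": effort.trap_xy[:, 1],
    }).to_csv(path, index=False)
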