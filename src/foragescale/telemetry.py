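"""Telemetry track containers, loading, gap-splitting, projection and summaries.

A :class:`Track` is the time-ordered sequence of GPS fixes for one deployment
(or one gap-split piece of a deployment).  Geographic coordinates are kept in
degrees (WGS84 convention); every metric stage of the framework (first-passage
time radii, kernel bandwidths, patch areas) operates on planar coordinates in
meters obtained with :func:`project_planar`, an azimuthal-equidistant
projection centered on the track's own centroid so that wide-ranging tracks
never straddle a projection-zone seam.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_008.8  # mean Earth radius (IUGG)

DEFAULT_SPLIT_GAP_S = 7 * 86_400.0  # split tracks at gaps longer than one week

#: default column mapping for delimited-text telemetry
DEFAULT_SCHEMA = {
    "id": "id",
    "timestamp": "timestamp",
    "lon": "lon",
    "lat": "lat",
    "species": "species",
    "site": "site",
}


@dataclass(eq=False)
class Track:
    """Time-ordered GPS fixes for one individual (or split piece thereof).

    Exactly one of (``lon``, ``lat``) or (``x``, ``y``) may be absent;
    :func:`project_planar` fills ``x``/``y`` from ``lon``/``lat``.
    Times are stored as seconds (float) since the first fix's epoch together
    with the absolute start timestamp, which keeps all downstream arithmetic
    in plain float seconds.
    """

    individual_id: str
    t: np.ndarray  # seconds, strictly increasing, t[0] == 0
    start_time: pd.Timestamp
    lon: np.ndarray | None = None
    lat: np.ndarray | None = None
    x: np.ndarray | None = None
    y: np.ndarray | None = None
    species: str = ""
    site: str = ""
    crs_note: str = ""
    split_suffix: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.size < 2:
            raise ValueError("a track needs at least 2 fixes")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        for name in ("lon", "lat", "x", "y"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.t.shape:
                    raise ValueError(f"{name} length differs from timestamps")
                if not np.all(np.isfinite(v)):
                    raise ValueError(f"non-finite {name} coordinate")
                setattr(self, name, v)
        if self.lon is None and self.x is None:
            raise ValueError("track needs lon/lat or x/y coordinates")

    @property
    def n_fixes(self) -> int:
        return self.t.size

    @property
    def label(self) -> str:
        return f"{self.individual_id}{self.split_suffix}"

    @property
    def is_projected(self) -> bool:
        return self.x is not None and self.y is not None

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.start_time + pd.to_timedelta(self.t, unit="s")

    def xy(self) -> np.ndarray:
        """(n, 2) planar coordinates in meters; requires a projected track."""
        if not self.is_projected:
            raise ValueError("track is not projected; call project_planar first")
        return np.column_stack([self.x, self.y])


@dataclass(frozen=True)
class TrackSummary:
    """Deployment summary in the conventional reporting schema."""

    individual_id: str
    species: str
    site: str
    n_relocations: int
    start_date: pd.Timestamp
    end_date: pd.Timestamp
    days_tracked: float
    total_distance_km: float
    km_per_day: float

    def as_row(self) -> dict:
        return {
            "id": self.individual_id,
            "species": self.species,
            "site": self.site,
            "n_relocations": self.n_relocations,
            "start_date": self.start_date.date().isoformat(),
            "end_date": self.end_date.date().isoformat(),
            "days": int(round(self.days_tracked)),
            "dist_km": round(self.total_distance_km, 2),
            "km_per_day": round(self.km_per_day, 2),
        }


def load_tracks(
    path,
    schema: dict | None = None,
    timestamp_format: str | None = None,
    sep: str = ",",
) -> list[Track]:
    """Read delimited-text telemetry into one :class:`Track` per individual.

    Fixes are sorted by time within each individual; duplicate timestamps keep
    the first occurrence (logged).  Individuals with fewer than two usable
    fixes are skipped with a warning.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, sep=sep)
    required = [schema["id"], schema["timestamp"]]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    geographic = schema["lon"] in df.columns and schema["lat"] in df.columns
    planar = "x" in df.columns and "y" in df.columns
    if not geographic and not planar:
        raise ValueError(
            f"missing coordinate columns: need {schema['lon']}/{schema['lat']} or x/y"
        )
    try:
        ts = pd.to_datetime(df[schema["timestamp"]], format=timestamp_format, utc=True)
    except (ValueError, TypeError) as exc:
        bad = None
        for i, v in enumerate(df[schema["timestamp"]]):
            try:
                pd.to_datetime(v, format=timestamp_format, utc=True)
            except (ValueError, TypeError):
                bad = i
                break
        raise ValueError(f"unparseable timestamp at data row {bad}: {exc}") from exc
    df = df.assign(__ts=ts)

    tracks: list[Track] = []
    for ind_id, g in df.groupby(schema["id"], sort=True):
        g = g.sort_values("__ts", kind="stable")
        dup = g["__ts"].duplicated(keep="first")
        if dup.any():
            logger.warning(
                "%s: dropping %d fix(es) with duplicated timestamps", ind_id, dup.sum()
            )
            g = g[~dup]
        if len(g) < 2:
            logger.warning("%s: fewer than 2 fixes, skipped", ind_id)
            continue
        start = g["__ts"].iloc[0]
        coords = (
            {"lon": g[schema["lon"]].to_numpy(float), "lat": g[schema["lat"]].to_numpy(float)}
            if geographic
            else {"x": g["x"].to_numpy(float), "y": g["y"].to_numpy(float)}
        )
        tracks.append(
            Track(
                individual_id=str(ind_id),
                t=(g["__ts"] - start).dt.total_seconds().to_numpy(),
                start_time=start,
                species=str(g[schema["species"]].iloc[0]) if schema["species"] in g else "",
                site=str(g[schema["site"]].iloc[0]) if schema["site"] in g else "",
                **coords,
            )
        )
    return tracks


def split_on_gaps(track: Track, max_gap: float = DEFAULT_SPLIT_GAP_S) -> list[Track]:
    """Split a track wherever the inter-fix gap strictly exceeds ``max_gap`` seconds.

    Split pieces get suffixes '', 'a', 'b', ... in temporal order; pieces left
    with fewer than 2 fixes are dropped (logged).
    """
    gaps = np.diff(track.t)
    cut_after = np.flatnonzero(gaps > max_gap)
    if cut_after.size == 0:
        return [track]
    bounds = np.concatenate([[0], cut_after + 1, [track.n_fixes]])
    suffixes = [""] + [chr(ord("a") + i) for i in range(len(bounds) - 2)]
    pieces: list[Track] = []
    for suffix, lo, hi in zip(suffixes, bounds[:-1], bounds[1:]):
        if hi - lo < 2:
            logger.warning("%s: dropping split piece with <2 fixes", track.individual_id)
            continue
        sl = slice(lo, hi)
        pieces.append(
            replace(
                track,
                t=track.t[sl] - track.t[lo],
                start_time=track.start_time + pd.Timedelta(seconds=track.t[lo]),
                lon=None if track.lon is None else track.lon[sl],
                lat=None if track.lat is None else track.lat[sl],
                x=None if track.x is None else track.x[sl],
                y=None if track.y is None else track.y[sl],
                split_suffix=suffix,
            )
        )
    return pieces


def _aeqd_forward(lon, lat, lon0, lat0):
    """Spherical azimuthal-equidistant forward projection (degrees -> meters)."""
    lam, phi = np.radians(lon), np.radians(lat)
    lam0, phi0 = np.radians(lon0), np.radians(lat0)
    cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    cos_c = np.clip(cos_c, -1.0, 1.0)
    c = np.arccos(cos_c)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c > 0, c / np.sin(c), 1.0)
    x = EARTH_RADIUS_M * k * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_M * k * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
    )
    return x, y


def _aeqd_inverse(x, y, lon0, lat0):
    """Spherical azimuthal-equidistant inverse projection (meters -> degrees)."""
    x = np.asarray(x, float) / EARTH_RADIUS_M
    y = np.asarray(y, float) / EARTH_RADIUS_M
    lam0, phi0 = np.radians(lon0), np.radians(lat0)
    c = np.hypot(x, y)
    with np.errstate(invalid="ignore", divide="ignore"):
        sin_c, cos_c = np.sin(c), np.cos(c)
        phi = np.where(
            c > 0,
            np.arcsin(np.clip(cos_c * np.sin(phi0) + y * sin_c * np.cos(phi0) / np.where(c > 0, c, 1.0), -1, 1)),
            phi0,
        )
        lam = np.where(
            c > 0,
            lam0 + np.arctan2(x * sin_c, c * np.cos(phi0) * cos_c - y * np.sin(phi0) * sin_c),
            lam0,
        )
    return np.degrees(lam), np.degrees(phi)


def project_planar(track: Track) -> Track:
    """Project lon/lat fixes to planar x/y meters.

    Azimuthal-equidistant, centered on the track centroid: distances from the
    center are exact great-circle distances, and the distortion of inter-fix
    distances stays negligible at foraging-trip extents.  The center is
    recorded in ``crs_note`` so the inverse (:func:`unproject_planar`) can
    restore geographic coordinates for export.
    """
    if track.lon is None or track.lat is None:
        raise ValueError("track has no geographic coordinates to project")
    if np.any(np.abs(track.lon) > 180) or np.any(np.abs(track.lat) > 90):
        raise ValueError("lon/lat outside valid ranges")
    lon0 = float(np.mean(track.lon))
    lat0 = float(np.mean(track.lat))
    x, y = _aeqd_forward(track.lon, track.lat, lon0, lat0)
    note = json.dumps({"proj": "aeqd", "lon_0": lon0, "lat_0": lat0, "R": EARTH_RADIUS_M})
    return replace(track, x=np.asarray(x, float), y=np.asarray(y, float), crs_note=note)


def unproject_planar(track: Track) -> Track:
    """Inverse of :func:`project_planar`, using the center stored in ``crs_note``."""
    if not track.is_projected:
        raise ValueError("track has no planar coordinates")
    meta = json.loads(track.crs_note)
    lon, lat = _aeqd_inverse(track.x, track.y, meta["lon_0"], meta["lat_0"])
    return replace(track, lon=np.asarray(lon, float), lat=np.asarray(lat, float))


def step_lengths(track: Track) -> np.ndarray:
    """Euclidean step lengths (m) between consecutive fixes of a projected track."""
    xy = track.xy()
    return np.hypot(*np.diff(xy, axis=0).T)


def summarize_track(track: Track) -> TrackSummary:
    """Deployment summary: relocations, span, total distance and km/day."""
    span_s = track.t[-1] - track.t[0]
    if span_s <= 0:
        raise ValueError("zero-duration track")
    days = span_s / 86_400.0
    dist_km = float(step_lengths(track).sum()) / 1000.0
    return TrackSummary(
        individual_id=track.label,
        species=track.species,
        site=track.site,
        n_relocations=track.n_fixes,
        start_date=track.start_time,
        end_date=track.timestamps[-1],
        days_tracked=days,
        total_distance_km=dist_km,
        km_per_day=dist_km / days,
    )


def summaries_to_frame(summaries: list[TrackSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.as_row() for s in summaries])


def track_to_geojson(track: Track) -> dict:
    """Track as a GeoJSON LineString feature (lon/lat, WGS84 convention)."""
    tr = track if track.lon is not None else unproject_planar(track)
    coords = [[round(float(lo), 7), round(float(la), 7)] for lo, la in zip(tr.lon, tr.lat)]
    return {
        "type": "Feature",
        "geometry": {"type": "LineString", "coordinates": coords},
        "properties": {
            "id": track.label,
            "species": track.species,
            "site": track.site,
            "start": str(track.start_time),
        },
    }
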