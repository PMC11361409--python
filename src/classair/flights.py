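"""Counting flight operations near school sites.

A flight counts toward a site's exposure when any track point is below the
altitude ceiling (750 m) while within the radius (one mile) of the site —
the "nearby flight" geofence.  Counts are tabulated per site, airport and
operation (arrival/departure), and summarised across a group of sites by
median and quartiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .units import EARTH_RADIUS_M, MILE_TO_M

DEFAULT_ALT_CEILING_M = 750.0
DEFAULT_RADIUS_M = MILE_TO_M


@dataclass(frozen=True)
class SchoolSite:
    school_id: str
    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not -90 <= self.latitude <= 90:
            raise ValueError("latitude out of range")
        if not -180 <= self.longitude <= 180:
            raise ValueError("longitude out of range")


@dataclass
class FlightTrack:
    """One flight: id, airport, operation, and its (time, lat, lon, alt) points."""

    flight_id: str
    airport: str
    operation: str  # "arrival" | "departure"
    points: pd.DataFrame  # columns: time, lat, lon, alt_m

    def __post_init__(self) -> None:
        if len(self.points) == 0:
            raise ValueError("track must have at least one point")
        if self.operation not in ("arrival", "departure"):
            raise ValueError("operation must be 'arrival' or 'departure'")
        lat = self.points["lat"].to_numpy()
        lon = self.points["lon"].to_numpy()
        if np.any((lat < -90) | (lat > 90)) or np.any((lon < -180) | (lon > 180)):
            raise ValueError("coordinates out of range")


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in metres (Earth radius 6371.0088 km)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(h))


def flight_near_site(
    track: FlightTrack,
    site: SchoolSite,
    alt_ceiling_m: float = DEFAULT_ALT_CEILING_M,
    radius_m: float = DEFAULT_RADIUS_M,
) -> bool:
    """True iff any point is strictly below the ceiling and strictly within
    the radius of the site.  Points with missing altitude are ignored; a
    track with no altitudes at all is not counted (with a warning)."""
    alt = pd.to_numeric(track.points["alt_m"], errors="coerce").to_numpy(dtype=float)
    valid = np.isfinite(alt)
    if not valid.any():
        warnings.warn(f"flight {track.flight_id}: no altitude data", stacklevel=2)
        return False
    low = valid & (alt < alt_ceiling_m)
    if not low.any():
        return False
    d = haversine_m(
        track.points["lat"].to_numpy()[low],
        track.points["lon"].to_numpy()[low],
        site.latitude,
        site.longitude,
    )
    return bool(np.any(d < radius_m))


def tracks_from_table(table: pd.DataFrame) -> list[FlightTrack]:
    """Group a flat point table (flight_id, airport, operation, time, lat,
    lon, alt_m) into :class:`FlightTrack` objects, one per flight_id."""
    tracks = []
    for fid, grp in table.groupby("flight_id", sort=True):
        airports = grp["airport"].unique()
        ops = grp["operation"].unique()
        if len(airports) > 1 or len(ops) > 1:
            warnings.warn(f"flight {fid}: inconsistent airport/operation labels; "
                          "using the first", stacklevel=2)
        tracks.append(
            FlightTrack(
                flight_id=str(fid),
                airport=str(airports[0]),
                operation=str(ops[0]),
                points=grp[["time", "lat", "lon", "alt_m"]].reset_index(drop=True),
            )
        )
    return tracks


def count_flights(
    tracks,
    sites,
    alt_ceiling_m: float = DEFAULT_ALT_CEILING_M,
    radius_m: float = DEFAULT_RADIUS_M,
) -> pd.DataFrame:
    """Count nearby flights per site x airport x operation.

    Each flight_id contributes at most once per site (duplicate ids are
    merged with a warning).  Returns a tidy frame with columns
    ``school_id, airport, operation, count`` including an ``all`` airport
    total and a ``total`` operation row per airport.
    """
    if isinstance(tracks, pd.DataFrame):
        tracks = tracks_from_table(tracks)
    seen: dict[str, FlightTrack] = {}
    for t in tracks:
        if t.flight_id in seen:
            warnings.warn(f"duplicate flight_id {t.flight_id}; counted once",
                          stacklevel=2)
            continue
        seen[t.flight_id] = t
    tracks = list(seen.values())
    airports = sorted({t.airport for t in tracks})
    rows = []
    for site in sites:
        near = [t for t in tracks
                if flight_near_site(t, site, alt_ceiling_m, radius_m)]
        for ap in airports + ["all"]:
            for op in ("arrival", "departure", "total"):
                n = sum(
                    1 for t in near
                    if (ap == "all" or t.airport == ap)
                    and (op == "total" or t.operation == op)
                )
                rows.append((site.school_id, ap, op, n))
    return pd.DataFrame(rows, columns=["school_id", "airport", "operation", "count"])


def summarize_counts(table: pd.DataFrame, sites=None) -> pd.DataFrame:
    """Median and 25th-75th percentile of per-site counts by airport/operation.

    ``sites`` optionally restricts to a subset of school_ids.  Quartiles use
    linear interpolation.
    """
    df = table
    if sites is not None:
        ids = {s.school_id if isinstance(s, SchoolSite) else s for s in sites}
        df = df[df["school_id"].isin(ids)]
        if df.empty:
            raise ValueError("no sites left after filtering")
    out = (
        df.groupby(["airport", "operation"])["count"]
        .agg(
            median="median",
            q25=lambda x: float(np.percentile(x, 25)),
            q75=lambda x: float(np.percentile(x, 75)),
            n_sites="size",
        )
        .reset_index()
    )
    return out
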