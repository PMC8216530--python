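"""Trip segmentation and trip-level foraging metrics for central-place foragers.

Fix streams (bird_id, timestamp, lon, lat) are cut into foraging trips —
maximal excursions beyond a radius around the colony — and each trip is
summarised by duration, maximum colony distance, distal point and bearing,
and the time share of each behavioural mode.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

FIX_COLUMNS = ["bird_id", "trip_id", "timestamp", "lon", "lat"]


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing_deg(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Initial great-circle bearing, degrees clockwise from north in [0, 360)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.degrees(np.arctan2(y, x)) % 360.0


def circular_mean_deg(bearings_deg) -> float:
    """Mean direction of angles in degrees; result in [0, 360)."""
    b = np.radians(np.asarray(bearings_deg, dtype=float))
    if b.size == 0:
        raise ValueError("no bearings")
    return float(np.degrees(np.arctan2(np.mean(np.sin(b)), np.mean(np.cos(b)))) % 360.0)


@dataclass
class Trip:
    """One foraging excursion: a contiguous, time-ordered block of fixes."""

    bird_id: str
    trip_id: str
    fixes: pd.DataFrame  # columns timestamp, lon, lat (+ extras), time-sorted

    @property
    def duration_h(self) -> float:
        ts = self.fixes["timestamp"]
        return (ts.iloc[-1] - ts.iloc[0]).total_seconds() / 3600.0


def split_trips(
    fixes: pd.DataFrame,
    colony: tuple[float, float],
    radius_km: float = 1.0,
    min_duration_min: float = 30.0,
) -> list[Trip]:
    """Segment per-bird fix streams into trips.

    A trip is a maximal run of fixes farther than ``radius_km`` from the
    colony, padded with the adjacent at-colony fix on each side when one
    exists; runs shorter than ``min_duration_min`` are discarded.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    if fixes.empty:
        return []
    trips: list[Trip] = []
    for bird_id, df in fixes.groupby("bird_id", sort=True):
        df = df.sort_values("timestamp").reset_index(drop=True)
        if df["timestamp"].duplicated().any():
            raise ValueError(f"duplicate timestamps for bird {bird_id}")
        away = haversine_km(df["lon"], df["lat"], colony[0], colony[1]) > radius_km
        away = np.asarray(away)
        # Runs of consecutive away fixes.
        edges = np.flatnonzero(np.diff(np.concatenate(([0], away.view(np.int8), [0]))))
        k = 0
        for start, stop in zip(edges[::2], edges[1::2]):
            lo = max(start - 1, 0)  # pad with at-colony neighbours
            hi = min(stop + 1, len(df))
            seg = df.iloc[lo:hi].reset_index(drop=True)
            dur_min = (seg["timestamp"].iloc[-1] - seg["timestamp"].iloc[0]).total_seconds() / 60.0
            if dur_min < min_duration_min:
                continue
            trips.append(Trip(str(bird_id), f"{bird_id}_t{k:03d}", seg))
            k += 1
    return trips


def step_features(trip: Trip) -> pd.DataFrame:
    """Per-step speed (km/h) and absolute turning angle (rad, [0, pi]).

    Speeds come from great-circle step lengths over time gaps; turn i is the
    absolute smallest signed change between the headings of steps i-1 and i
    (first step has no turn, reported NaN).  One row per step (n_fixes - 1).
    """
    df = trip.fixes
    if len(df) < 3:
        raise ValueError("trip must have at least 3 fixes")
    lon, lat = df["lon"].to_numpy(float), df["lat"].to_numpy(float)
    dt_h = np.diff(df["timestamp"].astype("int64").to_numpy()) / 3.6e12
    if np.any(dt_h <= 0):
        raise ValueError("non-increasing timestamps within trip")
    dist = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    speed = dist / dt_h
    heading = initial_bearing_deg(lon[:-1], lat[:-1], lon[1:], lat[1:])
    dh = np.diff(heading)
    turn = np.abs((dh + 180.0) % 360.0 - 180.0)  # smallest signed difference
    turn_rad = np.radians(np.concatenate(([np.nan], turn)))
    return pd.DataFrame(
        {
            "bird_id": trip.bird_id,
            "trip_id": trip.trip_id,
            "timestamp": df["timestamp"].iloc[:-1].to_numpy(),
            "lon": lon[:-1],
            "lat": lat[:-1],
            "speed_kmh": speed,
            "turn_rad": turn_rad,
        }
    )


def trip_metrics(
    trip: Trip, labels: np.ndarray | pd.Series, colony: tuple[float, float]
) -> dict:
    """Trip summary: duration, max colony distance, distal point/bearing,
    and the share of fixes in each behavioural mode.

    ``labels`` is one behavioural state per fix (missing allowed, excluded
    from the proportions' denominator).
    """
    labels = pd.Series(np.asarray(labels, dtype=object))
    if len(labels) != len(trip.fixes):
        raise ValueError("labels/fix length mismatch")
    lon = trip.fixes["lon"].to_numpy(float)
    lat = trip.fixes["lat"].to_numpy(float)
    d = haversine_km(lon, lat, colony[0], colony[1])
    i = int(np.argmax(d))
    ok = labels.notna()
    counts = labels[ok].value_counts()
    denom = max(int(ok.sum()), 1)
    props = {
        f"prop_{s}": float(counts.get(s, 0)) / denom
        for s in ("travel", "forage", "rest", "relocate")
    }
    return {
        "bird_id": trip.bird_id,
        "trip_id": trip.trip_id,
        "duration_h": trip.duration_h,
        "max_dist_colony_km": float(d[i]),
        "distal_lon": float(lon[i]),
        "distal_lat": float(lat[i]),
        "distal_bearing_deg": float(initial_bearing_deg(colony[0], colony[1], lon[i], lat[i])),
        **props,
    }


def trips_to_metrics_table(
    trips: list[Trip],
    labels_by_trip: dict[str, np.ndarray],
    colony: tuple[float, float],
) -> pd.DataFrame:
    """Tidy per-trip metrics table, one row per (bird_id, trip_id)."""
    rows = [trip_metrics(t, labels_by_trip[t.trip_id], colony) for t in trips]
    return pd.DataFrame(rows)
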