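"""From raw GPS + depth streams to regular, labelled, coverage-annotated trips.

Pipeline: split a GPS stream into foraging trips (distance/duration rule),
linearly interpolate each trip to the 1-s depth-sensor resolution, label
every second as dive/no-dive from the 2-m depth threshold, annotate the
coverage ratio (fraction of expected fixes actually recorded), and
optionally downsample to the 5/15/30-s analysis resolutions. Train/
validation/test splitting is done at the trip level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geo import haversine_m

ANALYSIS_RESOLUTIONS = (5, 15, 30)
DIVE_DEPTH_THRESHOLD_M = 2.0


@dataclass
class RawTrip:
    """Irregularly sampled GPS fixes of one foraging trip."""

    t: np.ndarray  # s, strictly increasing
    lon: np.ndarray
    lat: np.ndarray
    trip_id: str = "trip0"


@dataclass
class Trip:
    """Regularly sampled trip with per-position dive label and coverage.

    ``observed`` is False at linearly interpolated positions; ``coverage``
    is the fraction of expected fixes recorded in each position's sampling
    interval.
    """

    trip_id: str
    dt: int
    t: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    dive: np.ndarray  # bool
    observed: np.ndarray  # bool
    coverage: np.ndarray  # float in [0, 1]

    def __post_init__(self):
        n = len(self.t)
        if n < 2:
            raise ValueError("a trip needs at least 2 positions")
        if not all(len(a) == n for a in (self.lon, self.lat, self.dive, self.observed, self.coverage)):
            raise ValueError("all per-position vectors must have equal length")
        steps = np.diff(self.t)
        if not np.allclose(steps, self.dt):
            raise ValueError("timestamps must be arithmetic with step dt")
        if np.any(self.coverage < 0) or np.any(self.coverage > 1):
            raise ValueError("coverage must lie in [0, 1]")

    def __len__(self):
        return len(self.t)


@dataclass(frozen=True)
class DatasetSplit:
    train: tuple[str, ...]
    validation: tuple[str, ...]
    test: tuple[str, ...]
    seed: int
    fractions: tuple[float, float, float] = (0.5, 0.3, 0.2)


def split_trips(
    t: np.ndarray,
    lon: np.ndarray,
    lat: np.ndarray,
    colony: tuple[float, float],
    min_distance: float = 1000.0,
    min_duration: float = 600.0,
) -> list[RawTrip]:
    """Cut a time-sorted GPS stream into foraging trips.

    A trip is a maximal run of consecutive fixes further than
    ``min_distance`` metres from the colony that spans at least
    ``min_duration`` seconds.
    """
    t = np.asarray(t, dtype=float)
    if t.size == 0:
        return []
    away = haversine_m(lon, lat, colony[0], colony[1]) > min_distance
    trips = []
    idx = np.flatnonzero(away)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks + 1, [idx.size]))
    k = 0
    for a, b in zip(starts, stops):
        sel = idx[a:b]
        if len(sel) >= 2 and t[sel[-1]] - t[sel[0]] >= min_duration:
            trips.append(RawTrip(t=t[sel], lon=np.asarray(lon)[sel], lat=np.asarray(lat)[sel], trip_id=f"trip{k}"))
            k += 1
    return trips


def interpolate_1s(raw: RawTrip) -> Trip:
    """Linearly interpolate a trip to 1-s resolution.

    Positions are produced at every integer second between the first and
    last fix; ``observed`` is True exactly at seconds holding a recorded
    fix (nearest-second match). Dive labels and coverage are filled by
    :func:`label_dives` / :func:`coverage_ratio` afterwards; here dive is
    initialized to False and coverage to the observed mask.
    """
    if len(raw.t) < 2:
        raise ValueError("need at least 2 fixes to interpolate")
    t0, t1 = np.ceil(raw.t[0]), np.floor(raw.t[-1])
    tg = np.arange(t0, t1 + 1.0)
    lon = np.interp(tg, raw.t, raw.lon)
    lat = np.interp(tg, raw.t, raw.lat)
    observed = np.zeros(tg.size, dtype=bool)
    sec = np.round(raw.t).astype(int)
    sec = sec[(sec >= t0) & (sec <= t1)]
    observed[(sec - int(t0)).astype(int)] = True
    return Trip(
        trip_id=raw.trip_id,
        dt=1,
        t=tg,
        lon=lon,
        lat=lat,
        dive=np.zeros(tg.size, dtype=bool),
        observed=observed,
        coverage=observed.astype(float),
    )


def label_dives(
    trip: Trip,
    depth_t: np.ndarray,
    depth: np.ndarray,
    threshold: float = DIVE_DEPTH_THRESHOLD_M,
) -> Trip:
    """Attach dive labels: depth strictly greater than ``threshold`` metres.

    Each 1-s position is matched to the nearest depth sample within
    ±0.5 s; seconds with no depth sample are labelled non-dive.
    """
    if len(depth_t) == 0:
        raise ValueError("empty depth stream")
    depth_t = np.asarray(depth_t, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if np.any(depth < 0):
        raise ValueError("depth must be non-negative")
    j = np.clip(np.searchsorted(depth_t, trip.t), 1, len(depth_t) - 1)
    nearer_left = np.abs(trip.t - depth_t[j - 1]) <= np.abs(depth_t[j] - trip.t)
    j = np.where(nearer_left, j - 1, j)
    matched = np.abs(depth_t[j] - trip.t) <= 0.5
    trip.dive = matched & (depth[j] > threshold)
    return trip


def coverage_ratio(observed: np.ndarray, dt: int) -> np.ndarray:
    """Coverage per dt-resampled position: observed 1-s fixes / dt.

    For dt = 1 this is just the observed mask as 0/1 floats.
    """
    observed = np.asarray(observed)
    if dt == 1:
        return observed.astype(float)
    n = (len(observed) // dt) * dt
    return observed[:n].reshape(-1, dt).mean(axis=1)


def downsample(trip: Trip, dt: int, allow_any_dt: bool = False) -> Trip:
    """Downsample a 1-s trip to resolution ``dt``.

    Coordinates are decimated (every dt-th position kept); the dive label
    is the OR over each dt-second window (a window containing at least one
    dive second is a dive), coverage the window mean, observed the OR.
    """
    if trip.dt != 1:
        raise ValueError("downsample expects a 1-s trip")
    if dt not in ANALYSIS_RESOLUTIONS and not allow_any_dt:
        raise ValueError(f"dt must be one of {ANALYSIS_RESOLUTIONS} (or pass allow_any_dt)")
    n = (len(trip) // dt) * dt
    if n == 0:
        raise ValueError("trip shorter than one window")
    sel = np.arange(0, n, dt)
    blk = lambda a: a[:n].reshape(-1, dt)
    return Trip(
        trip_id=trip.trip_id,
        dt=dt,
        t=trip.t[sel],
        lon=trip.lon[sel],
        lat=trip.lat[sel],
        dive=blk(trip.dive).any(axis=1),
        observed=blk(trip.observed).any(axis=1),
        coverage=blk(trip.coverage.astype(float)).mean(axis=1),
    )


def split_dataset(
    trip_ids: list[str],
    fractions: tuple[float, float, float] = (0.5, 0.3, 0.2),
    seed: int = 0,
) -> DatasetSplit:
    """Seeded random trip-level partition into train/validation/test."""
    n = len(trip_ids)
    if n < 3:
        raise ValueError("need at least 3 trips to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(n * fractions[0] + 0.5)
    n_val = int(n * fractions[1] + 0.5)
    n_val = min(n_val, n - n_train - 1) if n_train + n_val >= n else n_val
    ids = np.asarray(trip_ids, dtype=object)
    return DatasetSplit(
        train=tuple(ids[order[:n_train]]),
        validation=tuple(ids[order[n_train : n_train + n_val]]),
        test=tuple(ids[order[n_train + n_val :]]),
        seed=seed,
        fractions=fractions,
    )


def deployment_to_trip(dep, trip_id: str | None = None) -> Trip:
    """Interpolate a (possibly gappy) deployment to a labelled 1-s trip."""
    raw = RawTrip(t=dep.gps_t, lon=dep.lon, lat=dep.lat, trip_id=trip_id or dep.trip_id)
    trip = interpolate_1s(raw)
    return label_dives(trip, dep.depth_t, dep.depth)
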