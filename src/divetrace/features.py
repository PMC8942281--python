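"""Input channels and fixed-length windows for the segmentation networks.

Each network consumes a 3-channel window of L = 20 consecutive positions:
step speed (z-scored on the training split), turning angle (scaled to
[-1, 1] by 1/pi) and coverage ratio (raw, already in [0, 1]).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from ._geo import haversine_m, initial_bearing_rad, wrap_angle
from .preprocess import Trip

WINDOW_LENGTH = 20


@dataclass(frozen=True)
class NormStats:
    """Speed-standardization statistics, fitted on the training split only."""

    speed_mean: float
    speed_sd: float
    fitted_on: str = ""

    def to_json(self) -> str:
        return json.dumps({"speed_mean": self.speed_mean, "speed_sd": self.speed_sd, "fitted_on": self.fitted_on})

    @classmethod
    def from_json(cls, s: str) -> "NormStats":
        return cls(**json.loads(s))


@dataclass
class WindowSet:
    """Stacked feature windows: x (N, 3, L), y (N, L) booleans."""

    x: np.ndarray
    y: np.ndarray
    trip_id: np.ndarray  # (N,) object
    start_index: np.ndarray  # (N,) int

    def __len__(self):
        return len(self.x)

    @classmethod
    def concatenate(cls, sets: list["WindowSet"]) -> "WindowSet":
        sets = [s for s in sets if len(s)]
        if not sets:
            L = WINDOW_LENGTH
            return cls(np.empty((0, 3, L)), np.empty((0, L), bool), np.empty(0, object), np.empty(0, int))
        return cls(
            np.concatenate([s.x for s in sets]),
            np.concatenate([s.y for s in sets]),
            np.concatenate([s.trip_id for s in sets]),
            np.concatenate([s.start_index for s in sets]),
        )


def step_speed(lon: np.ndarray, lat: np.ndarray, dt: float) -> np.ndarray:
    """Per-position ground speed (m/s) from consecutive-fix haversine
    distances; the first position copies the second's speed."""
    if len(lon) < 2:
        raise ValueError("need at least 2 positions")
    d = haversine_m(lon[:-1], lat[:-1], lon[1:], lat[1:])
    v = d / float(dt)
    return np.concatenate(([v[0]], v))


def turning_angle(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Signed heading change per position, wrapped to (-pi, pi].

    angle(i) = bearing(i-1 -> i) - bearing(i -> i+1); a left turn is
    positive and an about-turn maps to +pi. Endpoints get 0, as do trips
    shorter than 3 positions.
    """
    n = len(lon)
    out = np.zeros(n)
    if n < 3:
        return out
    b = initial_bearing_rad(lon[:-1], lat[:-1], lon[1:], lat[1:])
    out[1:-1] = wrap_angle(b[:-1] - b[1:])
    return out


def fit_norm_stats(trips: list[Trip], tag: str = "") -> NormStats:
    """Mean/sd of step speed over all positions of the training trips."""
    if not trips:
        raise ValueError("need at least one trip")
    speeds = np.concatenate([step_speed(t.lon, t.lat, t.dt) for t in trips])
    return NormStats(float(speeds.mean()), float(max(speeds.std(), 1e-6)), tag)


def trip_features(trip: Trip, norm: NormStats) -> np.ndarray:
    """The 3 x n feature matrix of a whole trip."""
    sp = (step_speed(trip.lon, trip.lat, trip.dt) - norm.speed_mean) / norm.speed_sd
    ang = turning_angle(trip.lon, trip.lat) / np.pi
    return np.stack([sp, ang, trip.coverage.astype(float)])


def make_windows(
    trip: Trip, norm: NormStats, L: int = WINDOW_LENGTH, stride: int = 1
) -> WindowSet:
    """Cut a trip into fixed-length windows starting at 0, stride, 2*stride...

    A trip shorter than L yields an empty set with a warning.
    """
    n = len(trip)
    if n < L:
        warnings.warn(f"trip {trip.trip_id} shorter than window length {L}; no windows")
        return WindowSet(np.empty((0, 3, L)), np.empty((0, L), bool), np.empty(0, object), np.empty(0, int))
    feats = trip_features(trip, norm)
    starts = np.arange(0, n - L + 1, stride)
    x = np.stack([feats[:, s : s + L] for s in starts])
    y = np.stack([trip.dive[s : s + L] for s in starts])
    return WindowSet(
        x=x,
        y=y,
        trip_id=np.array([trip.trip_id] * len(starts), dtype=object),
        start_index=starts,
    )


def make_window_dataset(
    trips: list[Trip], norm: NormStats, L: int = WINDOW_LENGTH, stride: int = 1
) -> WindowSet:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return WindowSet.concatenate([make_windows(t, norm, L, stride) for t in trips])
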