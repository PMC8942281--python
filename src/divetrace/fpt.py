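"""First-passage time (FPT) dive-probability baseline.

The first-passage time at a position is the time the animal takes to
cross a circle of radius r centred there — long passage times flag
area-restricted search, which for plunge-diving seabirds correlates with
diving. Here the passage time sums a forward and a backward first exit
(each linearly interpolated between the bracketing fixes and truncated at
the trip boundary when the circle is never exited). The analysis radius is
chosen by maximizing the variance of log passage times over a log-spaced
candidate grid, and passage times are converted to dive probabilities by
per-trip min-max normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._geo import haversine_m
from .preprocess import Trip
from .training import DiveProbSeries


@dataclass
class FPTProfile:
    candidate_radii: np.ndarray
    fpt: np.ndarray  # (n_positions, n_radii)
    selected_radius: float


def _one_side_exit(dists: np.ndarray, times: np.ndarray, radius: float) -> float:
    """Time to first crossing of ``radius`` along one direction.

    ``dists[k]``/``times[k]`` are distance from the centre and |t - t_i| of
    successive positions, starting at the centre (dists[0] = 0). Returns the
    (interpolated) crossing time, or the boundary time if never exited.
    """
    beyond = np.flatnonzero(dists > radius)
    if beyond.size == 0:
        return float(times[-1])
    j = int(beyond[0])
    d0, d1 = dists[j - 1], dists[j]
    frac = (radius - d0) / (d1 - d0)
    return float(times[j - 1] + frac * (times[j] - times[j - 1]))


def fpt(trip: Trip, radius: float) -> np.ndarray:
    """First-passage time (s) at every position for one radius."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    n = len(trip)
    out = np.empty(n)
    for i in range(n):
        d = haversine_m(trip.lon[i], trip.lat[i], trip.lon, trip.lat)
        fwd = _one_side_exit(d[i:], trip.t[i:] - trip.t[i], radius)
        bwd = _one_side_exit(d[: i + 1][::-1], trip.t[i] - trip.t[: i + 1][::-1], radius)
        out[i] = fwd + bwd
    return out


def default_radius_grid(trip: Trip, n: int = 20) -> np.ndarray:
    """Log-spaced candidate radii spanning step scale to 100x step scale."""
    d = haversine_m(trip.lon[:-1], trip.lat[:-1], trip.lon[1:], trip.lat[1:])
    d = d[d > 0]
    if d.size == 0:
        return np.logspace(1, 3, n)
    lo = max(np.percentile(d, 1), 1.0)
    hi = np.percentile(d, 99) * 100.0
    return np.logspace(np.log10(lo), np.log10(hi), n)


def fpt_select_radius(
    trip: Trip, candidate_radii: np.ndarray | None = None, use_log: bool = True
) -> FPTProfile:
    """Radius maximizing the variance of (log) passage times.

    Ties go to the smaller radius; if the passage times are constant at
    every radius, falls back to the median radius with a warning.
    """
    radii = default_radius_grid(trip) if candidate_radii is None else np.asarray(candidate_radii, float)
    if radii.size < 2:
        raise ValueError("need at least 2 candidate radii")
    radii = np.sort(radii)
    mat = np.column_stack([fpt(trip, r) for r in radii])
    vals = np.log(np.maximum(mat, 1e-12)) if use_log else mat
    var = vals.var(axis=0)
    if np.all(np.ptp(mat, axis=0) == 0):
        warnings.warn("passage times constant at every radius; falling back to median radius")
        sel = float(np.median(radii))
    else:
        sel = float(radii[int(np.argmax(var))])  # argmax takes first (smallest) on ties
    return FPTProfile(candidate_radii=radii, fpt=mat, selected_radius=sel)


def fpt_probability(passage_times: np.ndarray, trip_id: str = "trip0", dt: int = 1) -> DiveProbSeries:
    """Min-max normalization of passage times to [0, 1], per trip."""
    t = np.asarray(passage_times, dtype=float)
    if t.size == 0:
        raise ValueError("empty passage-time series")
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite passage times")
    lo, hi = t.min(), t.max()
    if hi == lo:
        warnings.warn("degenerate passage times (max == min); returning constant 0.5")
        p = np.full_like(t, 0.5)
    else:
        p = (t - lo) / (hi - lo)
    return DiveProbSeries(trip_id=trip_id, p=p, dt=dt)


def fpt_dive_probability(trip: Trip, candidate_radii: np.ndarray | None = None) -> DiveProbSeries:
    """Full FPT pipeline for one trip: select radius, normalize to [0, 1]."""
    prof = fpt_select_radius(trip, candidate_radii)
    times = prof.fpt[:, int(np.argmin(np.abs(prof.candidate_radii - prof.selected_radius)))]
    return fpt_probability(times, trip.trip_id, trip.dt)
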