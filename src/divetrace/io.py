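"""CSV schemas for GPS, TDR, processed trips and predictions.

GPS: ``timestamp,lon,lat,trip_id`` with ISO-8601 UTC timestamps.
TDR: ``timestamp,depth_m``. Truth (simulator only): ``timestamp,state,dive``.
Processed trip: ``t,lon,lat,dive,observed,coverage`` plus a JSON sidecar
with trip_id / dt / species tag. Predictions: ``t,lon,lat,p_dive``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Trip
from .simulate import STATES, RawDeployment

_EPOCH = pd.Timestamp("2020-01-01", tz="UTC")


def _iso(seconds: np.ndarray, day_offset: int) -> pd.Series:
    return (_EPOCH + pd.to_timedelta(seconds + day_offset * 86_400, unit="s")).strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )


def write_deployments(deps: list[RawDeployment], out_dir, with_truth: bool = True) -> None:
    """Write a simulated dataset as gps.csv / tdr.csv (/ truth.csv).

    Successive trips are placed on successive days so timestamps stay
    unique within each stream.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gps, tdr, truth = [], [], []
    for day, dep in enumerate(deps):
        gps.append(
            pd.DataFrame(
                {"timestamp": _iso(dep.gps_t, day), "lon": dep.lon, "lat": dep.lat, "trip_id": dep.trip_id}
            )
        )
        tdr.append(pd.DataFrame({"timestamp": _iso(dep.depth_t, day), "depth_m": dep.depth}))
        if with_truth and dep.true_states is not None:
            truth.append(
                pd.DataFrame(
                    {
                        "timestamp": _iso(dep.depth_t, day),
                        "state": [STATES[s] for s in dep.true_states],
                        "dive": (dep.depth > 2.0).astype(int),
                    }
                )
            )
    pd.concat(gps).to_csv(out / "gps.csv", index=False)
    pd.concat(tdr).to_csv(out / "tdr.csv", index=False)
    if truth:
        pd.concat(truth).to_csv(out / "truth.csv", index=False)


def read_deployments(in_dir) -> list[RawDeployment]:
    """Read gps.csv + tdr.csv back into per-trip deployments."""
    src = Path(in_dir)
    gps = pd.read_csv(src / "gps.csv", parse_dates=["timestamp"])
    tdr = pd.read_csv(src / "tdr.csv", parse_dates=["timestamp"])
    gps["t"] = (gps["timestamp"] - _EPOCH).dt.total_seconds()
    tdr["t"] = (tdr["timestamp"] - _EPOCH).dt.total_seconds()
    deps = []
    for trip_id, g in gps.groupby("trip_id", sort=False):
        t0, t1 = g["t"].min(), g["t"].max()
        d = tdr[(tdr["t"] >= t0) & (tdr["t"] <= t1 + 1)]
        deps.append(
            RawDeployment(
                gps_t=g["t"].to_numpy() - t0,
                lon=g["lon"].to_numpy(),
                lat=g["lat"].to_numpy(),
                depth_t=d["t"].to_numpy() - t0,
                depth=d["depth_m"].to_numpy(),
                trip_id=str(trip_id),
            )
        )
    return deps


def write_trip(trip: Trip, out_dir, species_tag: str = "") -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / f"{trip.trip_id}.csv"
    pd.DataFrame(
        {
            "t": trip.t,
            "lon": trip.lon,
            "lat": trip.lat,
            "dive": trip.dive.astype(int),
            "observed": trip.observed.astype(int),
            "coverage": trip.coverage,
        }
    ).to_csv(path, index=False)
    path.with_suffix(".json").write_text(
        json.dumps({"trip_id": trip.trip_id, "dt": trip.dt, "species_tag": species_tag})
    )
    return path


def read_trip(path) -> Trip:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path)
    return Trip(
        trip_id=meta["trip_id"],
        dt=int(meta["dt"]),
        t=df["t"].to_numpy(float),
        lon=df["lon"].to_numpy(float),
        lat=df["lat"].to_numpy(float),
        dive=df["dive"].to_numpy(bool),
        observed=df["observed"].to_numpy(bool),
        coverage=df["coverage"].to_numpy(float),
    )


def write_probs(trip: Trip, p: np.ndarray, path) -> None:
    pd.DataFrame({"t": trip.t, "lon": trip.lon, "lat": trip.lat, "p_dive": p}).to_csv(
        Path(path), index=False
    )
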