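import numpy as np
import pytest

from divetrace.experiments import make_dataset
from divetrace.preprocess import Trip


@pytest.fixture(scope="session")
def booby_trips_1s():
    """Small booby-like simulated dataset at 1-s resolution (8 trips)."""
    return make_dataset("booby_pescadores", 8, seed=11)


@pytest.fixture()
def straight_trip():
    """Equatorial trip moving due east at a constant 10 m/s, 1 fix/s."""
    n = 200
    t = np.arange(n, dtype=float)
    m_per_deg = 6_371_000.0 * np.pi / 180.0
    lon = 10.0 * t / m_per_deg
    lat = np.zeros(n)
    return Trip(
        trip_id="straight",
        dt=1,
        t=t,
        lon=lon,
        lat=lat,
        dive=np.zeros(n, bool),
        observed=np.ones(n, bool),
        coverage=np.ones(n),
    )


def make_trip(lon, lat, dt=1, dive=None, trip_id="toy"):
    n = len(lon)
    return Trip(
        trip_id=trip_id,
        dt=dt,
        t=np.arange(n, dtype=float) * dt,
        lon=np.asarray(lon, float),
        lat=np.asarray(lat, float),
        dive=np.zeros(n, bool) if dive is None else np.asarray(dive, bool),
        observed=np.ones(n, bool),
        coverage=np.ones(n),
    )
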