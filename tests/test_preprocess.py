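"""Trip splitting, interpolation, labelling, downsampling and data splits."""

import numpy as np
import pytest

from conftest import make_trip
from divetrace._geo import M_PER_DEG
from divetrace.preprocess import (
    RawTrip,
    Trip,
    coverage_ratio,
    downsample,
    interpolate_1s,
    label_dives,
    split_dataset,
    split_trips,
)

COLONY = (0.0, 0.0)


def _stream(dists_m, dt=60.0):
    """GPS stream at given distances (m) east of the colony."""
    t = np.arange(len(dists_m), dtype=float) * dt
    lon = np.asarray(dists_m, float) / M_PER_DEG
    return t, lon, np.zeros_like(lon)


class TestSplitTrips:
    def test_all_fixes_at_colony_yield_no_trips(self):
        t, lon, lat = _stream([0, 50, 100, 20])
        assert split_trips(t, lon, lat, COLONY) == []

    def test_single_excursion_is_one_trip(self):
        t, lon, lat = _stream([0] * 3 + [5000] * 20 + [0] * 3)
        trips = split_trips(t, lon, lat, COLONY, min_distance=1000, min_duration=600)
        assert len(trips) == 1
        assert len(trips[0].t) == 20

    def test_two_excursions_split_by_colony_visit(self):
        t, lon, lat = _stream([0, 5000, 5000, 5000, 0, 0, 6000, 6000, 6000, 0], dt=400.0)
        trips = split_trips(t, lon, lat, COLONY, min_distance=1000, min_duration=600)
        assert len(trips) == 2

    def test_short_excursion_dropped(self):
        t, lon, lat = _stream([0, 5000, 5000, 0], dt=60.0)  # 120 s away
        assert split_trips(t, lon, lat, COLONY, min_duration=600) == []

    def test_empty_input(self):
        assert split_trips(np.array([]), np.array([]), np.array([]), COLONY) == []


class TestInterpolate:
    def test_linear_midpoint(self):
        raw = RawTrip(t=np.array([0.0, 10.0]), lon=np.array([0.0, 0.001]), lat=np.zeros(2))
        trip = interpolate_1s(raw)
        assert len(trip) == 11
        assert trip.lon[5] == pytest.approx(0.0005)
        assert trip.observed[0] and trip.observed[10]
        assert trip.observed.sum() == 2

    def test_regular_input_idempotent(self):
        t = np.arange(30, dtype=float)
        raw = RawTrip(t=t, lon=t * 1e-5, lat=np.zeros(30))
        trip = interpolate_1s(raw)
        np.testing.assert_allclose(trip.lon, raw.lon)
        assert trip.observed.all()

    def test_gap_counts(self):
        raw = RawTrip(t=np.array([0.0, 4.0, 8.0]), lon=np.array([0, 4e-5, 8e-5]), lat=np.zeros(3))
        trip = interpolate_1s(raw)
        assert len(trip) == 9
        assert (~trip.observed).sum() == 6

    def test_single_fix_rejected(self):
        with pytest.raises(ValueError):
            interpolate_1s(RawTrip(t=np.array([0.0]), lon=np.zeros(1), lat=np.zeros(1)))


class TestLabelDives:
    @pytest.mark.parametrize("depth,expected", [(2.5, True), (2.0, False), (0.0, False)])
    def test_threshold_is_strict(self, depth, expected):
        trip = make_trip(np.zeros(5), np.zeros(5))
        label_dives(trip, np.arange(5, dtype=float), np.full(5, depth))
        assert bool(trip.dive.all()) is expected
        assert bool(trip.dive.any()) is expected

    def test_empty_depth_stream_rejected(self):
        trip = make_trip(np.zeros(5), np.zeros(5))
        with pytest.raises(ValueError):
            label_dives(trip, np.array([]), np.array([]))


class TestCoverage:
    def test_fully_observed(self):
        assert np.all(coverage_ratio(np.ones(20, bool), 5) == 1.0)

    def test_partial_window(self):
        obs = np.zeros(60, bool)
        obs[:45] = True
        assert coverage_ratio(obs, 60)[0] == pytest.approx(0.75)

    def test_fully_interpolated(self):
        assert np.all(coverage_ratio(np.zeros(15, bool), 5) == 0.0)


class TestDownsample:
    def test_any_dive_in_window_labels_dive(self):
        trip = make_trip(np.zeros(5), np.zeros(5), dive=[0, 0, 1, 0, 0])
        with pytest.raises(ValueError):
            downsample(trip, 5)  # needs >= 2 output positions
        trip10 = make_trip(np.zeros(10), np.zeros(10), dive=[0, 0, 1, 0, 0, 0, 0, 0, 0, 0])
        out = downsample(trip10, 5)
        np.testing.assert_array_equal(out.dive, [True, False])

    def test_all_zero_labels_stay_zero(self):
        trip = make_trip(np.zeros(60), np.zeros(60))
        assert not downsample(trip, 15).dive.any()

    def test_length_arithmetic(self):
        trip = make_trip(np.zeros(60), np.zeros(60))
        assert len(downsample(trip, 15)) == 4

    def test_invalid_dt_rejected_unless_allowed(self):
        trip = make_trip(np.zeros(60), np.zeros(60))
        with pytest.raises(ValueError):
            downsample(trip, 7)
        assert len(downsample(trip, 7, allow_any_dt=True)) == 8

    @pytest.mark.parametrize("dt", [5, 15, 30])
    def test_dive_label_conservation(self, dt):
        rng = np.random.default_rng(dt)
        dive = rng.random(240) < 0.05
        trip = make_trip(np.zeros(240), np.zeros(240), dive=dive)
        out = downsample(trip, dt)
        k = dive[: (240 // dt) * dt].sum()
        if k > 0:
            assert 1 <= out.dive.sum() <= k
        assert np.all(np.diff(out.t) == dt)

    def test_coverage_of_fully_observed_trip_is_one(self, booby_trips_1s):
        trip = booby_trips_1s[0]
        full = make_trip(trip.lon[:300], trip.lat[:300])
        for dt in (5, 15, 30):
            assert np.all(downsample(full, dt).coverage == 1.0)


class TestSplitDataset:
    def test_ten_trips_split_5_3_2(self):
        s = split_dataset([f"t{i}" for i in range(10)], seed=0)
        assert (len(s.train), len(s.validation), len(s.test)) == (5, 3, 2)

    def test_same_seed_reproduces(self):
        ids = [f"t{i}" for i in range(17)]
        assert split_dataset(ids, seed=4) == split_dataset(ids, seed=4)

    def test_full_study_trip_count_rounding(self):
        s = split_dataset([f"t{i}" for i in range(297)], seed=1)
        assert (len(s.train), len(s.validation), len(s.test)) == (149, 89, 59)

    def test_partition_is_disjoint_and_complete(self):
        ids = [f"t{i}" for i in range(23)]
        s = split_dataset(ids, seed=2)
        parts = set(s.train) | set(s.validation) | set(s.test)
        assert parts == set(ids)
        assert len(s.train) + len(s.validation) + len(s.test) == 23

    def test_too_few_trips_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(["a", "b"], seed=0)
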