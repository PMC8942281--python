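"""HMM baseline: enumeration oracle, EM properties, closed-form reductions."""

import itertools

import numpy as np
import pytest
from scipy import stats

from conftest import make_trip
from divetrace._geo import M_PER_DEG
from divetrace.hmm import (
    HmmSpec,
    forward_backward,
    hmm_dive_probability,
    hmm_fit,
    hmm_fit_sequences,
    select_dive_state,
    trip_steps_angles,
)


def toy_spec(n_states=3):
    means = np.array([10.0, 100.0, 400.0][:n_states])
    sds = np.array([5.0, 40.0, 100.0][:n_states])
    kappas = np.array([0.5, 1.0, 4.0][:n_states])
    A = np.full((n_states, n_states), 0.1 / (n_states - 1))
    np.fill_diagonal(A, 0.9)
    return HmmSpec(
        n_states=n_states,
        step_mean=means,
        step_sd=sds,
        angle_mean=np.zeros(n_states),
        angle_kappa=kappas,
        transition_matrix=A,
        initial_distribution=np.full(n_states, 1.0 / n_states),
        fitted=True,
    )


def sample_from_spec(spec, n, seed):
    """Generate (steps, angles, states) directly from an HmmSpec."""
    rng = np.random.default_rng(seed)
    states = np.empty(n, dtype=int)
    states[0] = rng.choice(spec.n_states, p=spec.initial_distribution)
    for t in range(1, n):
        states[t] = rng.choice(spec.n_states, p=spec.transition_matrix[states[t - 1]])
    shapes = (spec.step_mean / spec.step_sd) ** 2
    scales = spec.step_sd**2 / spec.step_mean
    steps = rng.gamma(shapes[states], scales[states])
    angles = rng.vonmises(spec.angle_mean[states], np.maximum(spec.angle_kappa[states], 1e-9))
    return steps, angles, states


def enumeration_posteriors(steps, angles, spec):
    """Brute-force forward-backward: sum over all K^T state sequences."""
    T = len(steps)
    K = spec.n_states
    shapes = (spec.step_mean / spec.step_sd) ** 2
    scales = spec.step_sd**2 / spec.step_mean
    b = np.empty((T, K))
    for k in range(K):
        b[:, k] = stats.gamma.pdf(steps, shapes[k], scale=scales[k]) * stats.vonmises.pdf(
            angles, spec.angle_kappa[k], loc=spec.angle_mean[k]
        )
    post = np.zeros((T, K))
    total = 0.0
    for seq in itertools.product(range(K), repeat=T):
        p = spec.initial_distribution[seq[0]] * b[0, seq[0]]
        for t in range(1, T):
            p *= spec.transition_matrix[seq[t - 1], seq[t]] * b[t, seq[t]]
        total += p
        for t in range(T):
            post[t, seq[t]] += p
    return post / total


def test_forward_backward_matches_enumeration():
    spec = toy_spec(3)
    for seed in range(3):
        steps, angles, _ = sample_from_spec(spec, 8, seed)
        gamma, _, _ = forward_backward(steps, angles, spec)
        expected = enumeration_posteriors(steps, angles, spec)
        np.testing.assert_allclose(gamma, expected, atol=1e-10)


def test_posteriors_sum_to_one():
    spec = toy_spec(3)
    steps, angles, _ = sample_from_spec(spec, 500, 1)
    gamma, _, _ = forward_backward(steps, angles, spec)
    np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-10)


def test_well_separated_states_recovered_pointwise():
    """Near-delta emissions: posteriors agree with generating states."""
    spec = toy_spec(2)
    spec.step_mean = np.array([1.0, 500.0])
    spec.step_sd = np.array([0.1, 10.0])
    steps, angles, states = sample_from_spec(spec, 2000, 3)
    gamma, _, _ = forward_backward(steps, angles, spec)
    agree = (gamma.argmax(axis=1) == states).mean()
    assert agree >= 0.99


def test_em_loglik_monotone():
    spec = toy_spec(3)
    data = [sample_from_spec(spec, 1500, s)[:2] for s in range(2)]
    from divetrace.hmm import _em, _init_spec

    init = _init_spec(np.concatenate([d[0] for d in data]), 3, np.random.default_rng(0), False)
    lls = []
    cur = init
    for _ in range(15):
        nxt = _em(data, cur, max_iter=1, tol=-1.0)
        lls.append(nxt.log_likelihood)
        cur = nxt
    diffs = np.diff(lls)
    assert np.all(diffs >= -1e-8)


def test_single_state_fit_is_pooled_mle():
    rng = np.random.default_rng(4)
    steps = rng.gamma(3.0, 50.0, 4000)
    angles = rng.vonmises(0.3, 2.0, 4000)
    spec = hmm_fit_sequences([(steps, angles)], n_states=1, seed=0, restarts=1, max_iter=5)
    # closed-form gamma MLE via scipy on the pooled sample
    a, _, scale = stats.gamma.fit(steps, floc=0)
    assert spec.step_mean[0] == pytest.approx(a * scale, rel=1e-3)
    kappa, loc, _ = stats.vonmises.fit(angles, fscale=1)
    assert spec.angle_mean[0] == pytest.approx(loc, abs=0.02)
    assert spec.angle_kappa[0] == pytest.approx(kappa, rel=0.02)


def test_parameter_recovery_three_states():
    """20k steps from a known 3-state model: gamma means within 10%,
    concentrations within 20% after state matching."""
    truth = toy_spec(3)
    data = [sample_from_spec(truth, 5000, s)[:2] for s in range(4)]
    fit = hmm_fit_sequences(data, n_states=3, seed=0, restarts=2, max_iter=120)
    order = np.argsort(fit.step_mean)
    means = fit.step_mean[order]
    kappas = fit.angle_kappa[order]
    np.testing.assert_allclose(means, truth.step_mean, rtol=0.10)
    np.testing.assert_allclose(kappas, truth.angle_kappa, rtol=0.20)


def test_degenerate_data_rejected():
    steps = np.full(100, 5.0)
    with pytest.raises(ValueError):
        hmm_fit_sequences([(steps, np.zeros(100))], 2)


def test_unfitted_spec_rejected():
    spec = toy_spec(2)
    spec.fitted = False
    with pytest.raises(ValueError):
        hmm_dive_probability(spec, make_trip(np.zeros(30), np.zeros(30)))


def test_trip_order_invariance():
    spec = toy_spec(2)
    trips = []
    for s in range(3):
        steps, angles, _ = sample_from_spec(spec, 400, s)
        heading = np.cumsum(angles)
        lon = np.concatenate(([0], np.cumsum(steps * np.sin(heading)))) / M_PER_DEG
        lat = np.concatenate(([0], np.cumsum(steps * np.cos(heading)))) / M_PER_DEG
        trips.append(make_trip(lon, lat, trip_id=f"t{s}"))
    a = hmm_fit(trips, 2, seed=0, restarts=1, max_iter=30)
    b = hmm_fit(trips[::-1], 2, seed=0, restarts=1, max_iter=30)
    np.testing.assert_allclose(np.sort(a.step_mean), np.sort(b.step_mean), rtol=1e-6)


def test_supervised_dive_state_selection():
    spec = toy_spec(2)
    spec.step_mean = np.array([1.0, 500.0])
    spec.step_sd = np.array([0.1, 10.0])
    steps, angles, states = sample_from_spec(spec, 600, 7)
    heading = np.cumsum(angles)
    lon = np.concatenate(([0], np.cumsum(steps * np.sin(heading)))) / M_PER_DEG
    lat = np.concatenate(([0], np.cumsum(steps * np.cos(heading)))) / M_PER_DEG
    dive = np.concatenate(([False], states == 0))  # short steps are dives
    trip = make_trip(lon, lat, dive=dive)
    assert select_dive_state(spec, [trip]) == 0
    assert select_dive_state(spec, None) == 0  # smallest-mean fallback
    series = hmm_dive_probability(spec, trip, [trip])
    assert len(series) == len(trip)
    assert np.all((series.p >= 0) & (series.p <= 1))
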