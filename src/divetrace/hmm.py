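"""Hidden Markov movement-model baseline.

Trajectories are represented as sequences of step lengths (gamma marginal
per state) and turning angles (von Mises marginal per state), with 3
behavioural states for booby-like datasets and 4 for cormorant-like ones
(traveling, searching, diving, resting). Parameters are fitted by
Baum-Welch EM with exact weighted maximum-likelihood M-steps: the gamma
shape solves ln k - psi(k) = ln(weighted mean) - weighted mean log, and
the von Mises concentration solves I1(k)/I0(k) = mean resultant length
(both by bracketed root finding, so the per-iteration log-likelihood is
monotone non-decreasing). The dive probability of a position is the
forward-backward posterior of the dive state; which state is "dive" is
chosen supervised (the state whose posterior best ranks the training
labels) when labels are available, else the state with the smallest mean
step length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats
from scipy.optimize import brentq

from ._geo import haversine_m
from .features import turning_angle
from .preprocess import Trip
from .training import DiveProbSeries

STEP_FLOOR_M = 1e-3


@dataclass
class HmmSpec:
    """Fitted gamma-step / von-Mises-angle HMM."""

    n_states: int
    step_mean: np.ndarray  # per-state gamma mean, m
    step_sd: np.ndarray  # per-state gamma sd, m
    angle_mean: np.ndarray  # per-state von Mises location, rad
    angle_kappa: np.ndarray  # per-state von Mises concentration
    transition_matrix: np.ndarray
    initial_distribution: np.ndarray
    log_likelihood: float = -np.inf
    dive_state_index: int | None = None
    fitted: bool = False

    def __post_init__(self):
        tm = np.asarray(self.transition_matrix, float)
        if np.max(np.abs(tm.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(self.step_mean <= 0) or np.any(self.step_sd <= 0) or np.any(self.angle_kappa < 0):
            raise ValueError("gamma parameters must be positive, kappa non-negative")


def trip_steps_angles(trip: Trip) -> tuple[np.ndarray, np.ndarray]:
    """Step lengths (m, floored at 1 mm) and turning angles of a trip.

    Steps are between consecutive positions (n-1 of them); the angle of a
    zero-length step is 0 by convention.
    """
    d = haversine_m(trip.lon[:-1], trip.lat[:-1], trip.lon[1:], trip.lat[1:])
    ang = turning_angle(trip.lon, trip.lat)[1:]  # align angle at step end
    return np.maximum(d, STEP_FLOOR_M), ang


def _log_emission(steps: np.ndarray, angles: np.ndarray, spec: HmmSpec) -> np.ndarray:
    """(T, K) log emission densities."""
    T = len(steps)
    out = np.empty((T, spec.n_states))
    for k in range(spec.n_states):
        shape = (spec.step_mean[k] / spec.step_sd[k]) ** 2
        scale = spec.step_sd[k] ** 2 / spec.step_mean[k]
        out[:, k] = stats.gamma.logpdf(steps, shape, scale=scale)
        if spec.angle_kappa[k] > 1e-10:
            out[:, k] += stats.vonmises.logpdf(angles, spec.angle_kappa[k], loc=spec.angle_mean[k])
        else:
            out[:, k] += -np.log(2.0 * np.pi)
    return out


def forward_backward(
    steps: np.ndarray, angles: np.ndarray, spec: HmmSpec
) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled forward-backward. Returns (posteriors (T,K), xi_sum (K,K), loglik)."""
    logb = _log_emission(steps, angles, spec)
    b = np.exp(logb - logb.max(axis=1, keepdims=True))
    T, K = b.shape
    A = spec.transition_matrix
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = spec.initial_distribution * b[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * b[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, K))
    beta[-1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (b[t + 1] * beta[t + 1])) / c[t + 1]
        xi = alpha[t][:, None] * A * (b[t + 1] * beta[t + 1])[None, :] / c[t + 1]
        xi_sum += xi
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.sum(np.log(c)) + np.sum(logb.max(axis=1)))
    return gamma, xi_sum, loglik


def _gamma_wmle(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted gamma MLE; returns (mean, sd)."""
    wsum = w.sum()
    m = float(np.dot(w, x) / wsum)
    mlog = float(np.dot(w, np.log(x)) / wsum)
    s = np.log(m) - mlog
    if s <= 0:
        return m, max(m * 1e-3, 1e-6)
    f = lambda k: np.log(k) - special.digamma(k) - s
    lo, hi = 1e-3, 1e6
    if f(lo) < 0:
        k = lo
    elif f(hi) > 0:
        k = hi
    else:
        k = brentq(f, lo, hi, xtol=1e-12)
    return m, float(m / np.sqrt(k))


def _vonmises_wmle(theta: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted von Mises MLE; returns (mean direction, kappa)."""
    wsum = w.sum()
    C = float(np.dot(w, np.cos(theta)) / wsum)
    S = float(np.dot(w, np.sin(theta)) / wsum)
    mu = float(np.arctan2(S, C))
    R = min(np.hypot(C, S), 1.0 - 1e-12)
    if R < 1e-8:
        return mu, 0.0
    f = lambda k: special.i1e(k) / special.i0e(k) - R
    hi = 1e6
    if f(hi) < 0:
        return mu, hi
    return mu, float(brentq(f, 1e-10, hi, xtol=1e-12))


def _init_spec(
    steps: np.ndarray, n_states: int, rng: np.random.Generator, perturb: bool
) -> HmmSpec:
    # k-quantile split of step lengths seeds the state means
    qs = np.quantile(steps, np.linspace(0, 1, n_states + 1))
    means, sds = [], []
    for k in range(n_states):
        sel = steps[(steps >= qs[k]) & (steps <= qs[k + 1])]
        if sel.size < 2:
            sel = steps
        means.append(max(sel.mean(), STEP_FLOOR_M))
        sds.append(max(sel.std(), means[-1] * 0.1))
    means = np.array(means)
    sds = np.array(sds)
    if perturb:
        means = means * rng.uniform(0.7, 1.3, n_states)
        sds = sds * rng.uniform(0.7, 1.3, n_states)
    A = np.full((n_states, n_states), 0.1 / max(n_states - 1, 1))
    np.fill_diagonal(A, 0.9)
    A /= A.sum(axis=1, keepdims=True)
    return HmmSpec(
        n_states=n_states,
        step_mean=means,
        step_sd=sds,
        angle_mean=np.zeros(n_states),
        angle_kappa=np.ones(n_states),
        transition_matrix=A,
        initial_distribution=np.full(n_states, 1.0 / n_states),
    )


def hmm_fit(
    trips: list[Trip],
    n_states: int,
    seed: int = 0,
    restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> HmmSpec:
    """Baum-Welch fit over a set of same-resolution trips; best of restarts."""
    return hmm_fit_sequences([trip_steps_angles(t) for t in trips], n_states, seed, restarts, max_iter, tol)


def hmm_fit_sequences(
    data: list[tuple[np.ndarray, np.ndarray]],
    n_states: int,
    seed: int = 0,
    restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> HmmSpec:
    """Baum-Welch fit on raw (steps, angles) sequences; best of restarts."""
    pooled = np.concatenate([s for s, _ in data])
    if np.ptp(pooled) < 1e-12:
        raise ValueError("degenerate data: all step lengths equal")
    rng = np.random.default_rng(seed)
    best: HmmSpec | None = None
    for r in range(restarts):
        spec = _init_spec(pooled, n_states, rng, perturb=r > 0)
        spec = _em(data, spec, max_iter, tol)
        if best is None or spec.log_likelihood > best.log_likelihood:
            best = spec
    best.fitted = True
    return best


def _em(data, spec: HmmSpec, max_iter: int, tol: float) -> HmmSpec:
    K = spec.n_states
    prev_ll = -np.inf
    for _ in range(max_iter):
        ll = 0.0
        g_all, xi_tot, init_tot = [], np.zeros((K, K)), np.zeros(K)
        for steps, angles in data:
            gamma, xi, l = forward_backward(steps, angles, spec)
            g_all.append(gamma)
            xi_tot += xi
            init_tot += gamma[0]
            ll += l
        gcat = np.concatenate(g_all)
        steps_cat = np.concatenate([s for s, _ in data])
        ang_cat = np.concatenate([a for _, a in data])
        sm, ss, am, ak = [], [], [], []
        for k in range(K):
            w = gcat[:, k] + 1e-300
            m, sd = _gamma_wmle(steps_cat, w)
            mu, kappa = _vonmises_wmle(ang_cat, w)
            sm.append(m)
            ss.append(sd)
            am.append(mu)
            ak.append(kappa)
        A = xi_tot / np.maximum(xi_tot.sum(axis=1, keepdims=True), 1e-300)
        A = A / A.sum(axis=1, keepdims=True)
        spec = HmmSpec(
            n_states=K,
            step_mean=np.array(sm),
            step_sd=np.array(ss),
            angle_mean=np.array(am),
            angle_kappa=np.minimum(np.array(ak), 1e4),
            transition_matrix=A,
            initial_distribution=init_tot / init_tot.sum(),
            log_likelihood=ll,
        )
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            break
        prev_ll = ll
    return spec


def _pairwise_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    pos = scores[labels]
    neg = scores[~labels]
    if pos.size == 0 or neg.size == 0:
        return 0.5
    greater = (pos[:, None] > neg[None, :]).mean()
    ties = (pos[:, None] == neg[None, :]).mean()
    return float(greater + 0.5 * ties)


def select_dive_state(
    spec: HmmSpec, labelled_trips: list[Trip] | None = None
) -> int:
    """Pick the dive state: supervised by ranking power when labels are
    given, else the state with the smallest mean step length."""
    if labelled_trips:
        aucs = np.zeros(spec.n_states)
        for trip in labelled_trips:
            steps, angles = trip_steps_angles(trip)
            gamma, _, _ = forward_backward(steps, angles, spec)
            y = trip.dive[1:]
            for k in range(spec.n_states):
                aucs[k] += _pairwise_auc(gamma[:, k], y)
        return int(np.argmax(aucs))
    return int(np.argmin(spec.step_mean))


def hmm_dive_probability(
    spec: HmmSpec, trip: Trip, labelled_train_trips: list[Trip] | None = None
) -> DiveProbSeries:
    """Posterior probability of the dive state per position.

    The first position (which has no incoming step) duplicates the second
    position's posterior so the series matches the trip length.
    """
    if not spec.fitted:
        raise ValueError("HMM spec is not fitted")
    if spec.dive_state_index is None:
        spec.dive_state_index = select_dive_state(spec, labelled_train_trips)
    steps, angles = trip_steps_angles(trip)
    gamma, _, _ = forward_backward(steps, angles, spec)
    p = gamma[:, spec.dive_state_index]
    p = np.concatenate(([p[0]], p))
    return DiveProbSeries(trip_id=trip.trip_id, p=np.clip(p, 0.0, 1.0), dt=trip.dt)
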