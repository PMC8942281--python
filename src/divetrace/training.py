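"""Supervised training of the window-segmentation networks.

Loss is a weighted binary cross-entropy: dive seconds are rare (0.2-9.4%
of positions), so errors on the dive class are up-weighted — by 30 for
booby-like and 5 for cormorant-like datasets. Optimization is Adam at a
fixed learning rate of 0.001 with seeded mini-batch shuffling; training
stops as soon as the validation loss stops improving (patience in epochs)
and the best-validation weights are returned. Whole-trip prediction runs
the network on every stride-1 window and averages, per position, the
probabilities of all windows covering it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import NormStats, WindowSet, make_windows
from .networks import ModelBundle, backward, build, forward
from .preprocess import Trip

P_CLIP = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    class_weight: float = 30.0
    learning_rate: float = 0.001
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.class_weight <= 0 or self.learning_rate <= 0 or self.patience < 1:
            raise ValueError("class_weight and learning_rate must be positive, patience >= 1")


@dataclass
class LossHistory:
    train_loss: list[float] = field(default_factory=list)
    validation_loss: list[float] = field(default_factory=list)

    @property
    def stopped_epoch(self) -> int:
        return len(self.validation_loss)

    @property
    def best_epoch(self) -> int:
        return int(np.argmin(self.validation_loss)) + 1


@dataclass
class DiveProbSeries:
    """Per-position dive probability for one trip."""

    trip_id: str
    p: np.ndarray
    dt: int

    def __post_init__(self):
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise ValueError("probabilities must lie in [0, 1]")

    def __len__(self):
        return len(self.p)


def weighted_bce(p: np.ndarray, y: np.ndarray, w: float = 1.0) -> float:
    """Mean over elements of -[w y ln p + (1 - y) ln(1 - p)].

    Probabilities are clipped to [1e-7, 1 - 1e-7] for numerical safety.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs y {y.shape}")
    pc = np.clip(p, P_CLIP, 1.0 - P_CLIP)
    return float(np.mean(-(w * y * np.log(pc) + (1.0 - y) * np.log1p(-pc))))


def weighted_bce_grad(p: np.ndarray, y: np.ndarray, w: float) -> np.ndarray:
    """d(mean weighted BCE)/dp, elementwise, with matching clipping."""
    pc = np.clip(p, P_CLIP, 1.0 - P_CLIP)
    y = np.asarray(y, dtype=float)
    return (-(w * y / pc) + (1.0 - y) / (1.0 - pc)) / p.size


class Adam:
    """Standard Adam (beta1 0.9, beta2 0.999, eps 1e-8) over a param dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.001):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)


def _dataset_loss(bundle: ModelBundle, ws: WindowSet, w: float, batch: int = 512) -> float:
    tot = 0.0
    n = 0
    for i in range(0, len(ws), batch):
        p = forward(bundle, ws.x[i : i + batch])
        tot += weighted_bce(p, ws.y[i : i + batch], w) * p.size
        n += p.size
    return tot / n


def train(
    bundle: ModelBundle,
    train_windows: WindowSet,
    val_windows: WindowSet,
    cfg: TrainConfig,
) -> tuple[ModelBundle, LossHistory]:
    """Train a bundle; returns the best-validation-epoch weights.

    The input bundle is not modified. Raises on empty window sets and
    aborts with a diagnostic if the loss goes non-finite.
    """
    if len(train_windows) == 0 or len(val_windows) == 0:
        raise ValueError("train and validation window sets must be non-empty")
    model = bundle.copy()
    opt = Adam(model.params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    hist = LossHistory()
    best = model.copy()
    best_val = np.inf
    since_best = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_windows))
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            caches: list = []
            p = forward(model, train_windows.x[idx], caches)
            gp = weighted_bce_grad(p, train_windows.y[idx], cfg.class_weight)
            grads = backward(model, caches, gp)
            opt.step(model.params, grads)
        tl = _dataset_loss(model, train_windows, cfg.class_weight)
        vl = _dataset_loss(model, val_windows, cfg.class_weight)
        if not (np.isfinite(tl) and np.isfinite(vl)):
            raise FloatingPointError(f"non-finite loss at epoch {epoch + 1}: train {tl}, val {vl}")
        hist.train_loss.append(tl)
        hist.validation_loss.append(vl)
        if vl < best_val:
            best_val = vl
            best = model.copy()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    best.norm_stats = bundle.norm_stats
    best.meta = dict(bundle.meta)
    best.meta.update(
        class_weight=cfg.class_weight,
        seed=cfg.seed,
        epochs_trained=hist.stopped_epoch,
        best_epoch=hist.best_epoch,
    )
    return best, hist


def fine_tune(
    pretrained: ModelBundle,
    train_windows: WindowSet,
    val_windows: WindowSet,
    cfg: TrainConfig,
    norm_stats: NormStats | None = None,
) -> tuple[ModelBundle, LossHistory]:
    """Same procedure as :func:`train`, initialized from pretrained weights.

    All layers stay unfrozen. ``norm_stats`` should be refitted on the new
    training trips (the windows are assumed already standardized with them).
    """
    init = pretrained.copy()
    if norm_stats is not None:
        init.norm_stats = norm_stats
    init.meta["finetuned_from"] = pretrained.meta.get("name", pretrained.kind)
    if cfg.max_epochs == 0:
        return init, LossHistory()
    return train(init, train_windows, val_windows, cfg)


def predict_trip(bundle: ModelBundle, trip: Trip, batch: int = 512) -> DiveProbSeries:
    """Window-mean dive probability over every stride-1 window of a trip.

    The probability at position i is the arithmetic mean of that
    position's probability over all 20-position windows containing it.
    """
    if bundle.norm_stats is None:
        raise ValueError("bundle has no normalization statistics")
    L = bundle.spec.window_length
    if len(trip) < L:
        raise ValueError(f"trip length {len(trip)} < window length {L}")
    ws = make_windows(trip, bundle.norm_stats, L=L, stride=1)
    sums = np.zeros(len(trip))
    counts = np.zeros(len(trip))
    for i in range(0, len(ws), batch):
        p = forward(bundle, ws.x[i : i + batch])
        for j, s in enumerate(ws.start_index[i : i + batch]):
            sums[s : s + L] += p[j]
            counts[s : s + L] += 1.0
    return DiveProbSeries(trip_id=trip.trip_id, p=sums / counts, dt=trip.dt)
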