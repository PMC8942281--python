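"""The three window-segmentation architectures, implemented in numpy.

All three map a 3-channel, 20-position feature window to 20 per-position
dive probabilities through a sigmoid head:

* FCNet  — multilayer perceptron: flatten(3x20) -> 100 -> 500 -> 500 -> 500
  -> 20, ReLU between hidden layers (567,620 parameters).
* CNNet  — fully convolutional, 'same' padding: 3->16 (k3) -> 16->32 (k3)
  -> 32->32 (k3) -> 32->1 (k1), ReLU then sigmoid (4,865 parameters).
* UNet   — one-level encoder/decoder with skip connection: encoder
  3->24->24 (k3), max-pool 2 (20 -> 10), bottleneck 24->48->48 (k3),
  transposed-conv upsample 48->24 (k2, stride 2, 10 -> 20), concatenate
  with the encoder output (48 channels), decoder 48->24->24 (k3), head
  24->1 (k1) (20,041 parameters).

Layers carry explicit forward/backward passes in float64; training uses
these gradients with Adam (see :mod:`divetrace.training`). Weight
initialization is uniform fan-in scaled and fully seeded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import NormStats

ARCHITECTURES = ("FCNET", "CNNET", "UNET")
INPUT_CHANNELS = 3
WINDOW_LENGTH = 20


# ---------------------------------------------------------------------------
# layer specs and parameter counting


@dataclass(frozen=True)
class LayerSpec:
    name: str
    op: str  # dense | conv | convtranspose | maxpool | concat
    fan_in: int = 0
    fan_out: int = 0
    kernel: int = 0
    activation: str = ""

    @property
    def n_params(self) -> int:
        if self.op == "dense":
            return self.fan_in * self.fan_out + self.fan_out
        if self.op in ("conv", "convtranspose"):
            return self.fan_in * self.fan_out * self.kernel + self.fan_out
        return 0


@dataclass(frozen=True)
class ArchitectureSpec:
    kind: str
    layers: tuple[LayerSpec, ...]
    input_channels: int = INPUT_CHANNELS
    window_length: int = WINDOW_LENGTH


_FCNET_LAYERS = (
    LayerSpec("fc1", "dense", 60, 100, activation="relu"),
    LayerSpec("fc2", "dense", 100, 500, activation="relu"),
    LayerSpec("fc3", "dense", 500, 500, activation="relu"),
    LayerSpec("fc4", "dense", 500, 500, activation="relu"),
    LayerSpec("head", "dense", 500, 20, activation="sigmoid"),
)

_CNNET_LAYERS = (
    LayerSpec("conv1", "conv", 3, 16, 3, "relu"),
    LayerSpec("conv2", "conv", 16, 32, 3, "relu"),
    LayerSpec("conv3", "conv", 32, 32, 3, "relu"),
    LayerSpec("head", "conv", 32, 1, 1, "sigmoid"),
)

_UNET_LAYERS = (
    LayerSpec("enc1", "conv", 3, 24, 3, "relu"),
    LayerSpec("enc2", "conv", 24, 24, 3, "relu"),
    LayerSpec("pool", "maxpool"),
    LayerSpec("mid1", "conv", 24, 48, 3, "relu"),
    LayerSpec("mid2", "conv", 48, 48, 3, "relu"),
    LayerSpec("up", "convtranspose", 48, 24, 2, ""),
    LayerSpec("skip", "concat"),
    LayerSpec("dec1", "conv", 48, 24, 3, "relu"),
    LayerSpec("dec2", "conv", 24, 24, 3, "relu"),
    LayerSpec("head", "conv", 24, 1, 1, "sigmoid"),
)

_SPECS = {
    "FCNET": ArchitectureSpec("FCNET", _FCNET_LAYERS),
    "CNNET": ArchitectureSpec("CNNET", _CNNET_LAYERS),
    "UNET": ArchitectureSpec("UNET", _UNET_LAYERS),
}


def architecture_spec(kind: str) -> ArchitectureSpec:
    kind = kind.upper()
    if kind not in _SPECS:
        raise ValueError(f"unknown architecture {kind!r}; valid: {', '.join(ARCHITECTURES)}")
    return _SPECS[kind]


def count_parameters(spec: ArchitectureSpec | str) -> int:
    """Trainable-parameter count from the layer table (weights + biases)."""
    if isinstance(spec, str):
        spec = architecture_spec(spec)
    return sum(l.n_params for l in spec.layers)


# ---------------------------------------------------------------------------
# primitive ops (forward + backward), float64, batch-first


def _relu(z):
    return np.maximum(z, 0.0)


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _dense_fwd(x, W, b, cache):
    cache["x"] = x
    return x @ W.T + b


def _dense_bwd(gy, W, cache, grads, name):
    grads[f"{name}.W"] += gy.T @ cache["x"]
    grads[f"{name}.b"] += gy.sum(axis=0)
    return gy @ W


def _conv_fwd(x, W, b, cache):
    # x: (N, C, L); W: (O, C, k); 'same' zero padding for odd k
    k = W.shape[2]
    p = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (N, C, L, k)
    cache["win"] = win
    cache["shape"] = x.shape
    cache["pad"] = p
    return np.einsum("nclk,ock->nol", win, W, optimize=True) + b[None, :, None]


def _conv_bwd(gy, W, cache, grads, name):
    grads[f"{name}.W"] += np.einsum("nclk,nol->ock", cache["win"], gy, optimize=True)
    grads[f"{name}.b"] += gy.sum(axis=(0, 2))
    N, C, L = cache["shape"]
    p = cache["pad"]
    k = W.shape[2]
    gxp = np.zeros((N, C, L + 2 * p))
    for j in range(k):
        gxp[:, :, j : j + L] += np.einsum("nol,ocj->ncl", gy, W[:, :, j : j + 1], optimize=True)[..., :]
    return gxp[:, :, p : p + L] if p else gxp


def _convtranspose_fwd(x, W, b, cache):
    # x: (N, C, L); W: (C, O, k), stride = kernel = 2 -> (N, O, 2L)
    N, C, L = x.shape
    k = W.shape[2]
    cache["x"] = x
    y = np.empty((N, W.shape[1], L * k))
    for j in range(k):
        y[:, :, j::k] = np.einsum("ncl,coj->nol", x, W[:, :, j : j + 1], optimize=True)
    return y + b[None, :, None]


def _convtranspose_bwd(gy, W, cache, grads, name):
    x = cache["x"]
    k = W.shape[2]
    gx = np.zeros_like(x)
    for j in range(k):
        gyj = gy[:, :, j::k]
        grads[f"{name}.W"][:, :, j] += np.einsum("ncl,nol->co", x, gyj, optimize=True)
        gx += np.einsum("nol,coj->ncl", gyj, W[:, :, j : j + 1], optimize=True)
    grads[f"{name}.b"] += gy.sum(axis=(0, 2))
    return gx


def _maxpool2_fwd(x, cache):
    N, C, L = x.shape
    xr = x.reshape(N, C, L // 2, 2)
    arg = xr.argmax(axis=3)
    cache["arg"] = arg
    cache["shape"] = x.shape
    return xr.max(axis=3)


def _maxpool2_bwd(gy, cache):
    N, C, L = cache["shape"]
    gx = np.zeros((N, C, L // 2, 2))
    np.put_along_axis(gx, cache["arg"][..., None], gy[..., None], axis=3)
    return gx.reshape(N, C, L)


# ---------------------------------------------------------------------------
# model bundle


@dataclass
class ModelBundle:
    """An architecture plus its weights, normalization stats and metadata."""

    spec: ArchitectureSpec
    params: dict[str, np.ndarray]
    norm_stats: NormStats | None = None
    meta: dict = field(default_factory=dict)

    @property
    def kind(self) -> str:
        return self.spec.kind

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def copy(self) -> "ModelBundle":
        return ModelBundle(
            spec=self.spec,
            params={k: v.copy() for k, v in self.params.items()},
            norm_stats=self.norm_stats,
            meta=dict(self.meta),
        )

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}

    def save(self, path) -> None:
        """Checkpoint: .npz weight store + JSON manifest side by side."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        manifest = {
            "kind": self.kind,
            "n_params": self.n_params(),
            "norm_stats": None
            if self.norm_stats is None
            else {"speed_mean": self.norm_stats.speed_mean, "speed_sd": self.norm_stats.speed_sd, "fitted_on": self.norm_stats.fitted_on},
            "meta": self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, path) -> "ModelBundle":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        spec = architecture_spec(manifest["kind"])
        with np.load(path.with_suffix(".npz")) as z:
            params = {k: z[k] for k in z.files}
        got = int(sum(p.size for p in params.values()))
        if got != count_parameters(spec):
            raise ValueError(f"checkpoint holds {got} parameters, spec expects {count_parameters(spec)}")
        ns = manifest["norm_stats"]
        return cls(
            spec=spec,
            params=params,
            norm_stats=None if ns is None else NormStats(**ns),
            meta=manifest.get("meta", {}),
        )


def build(kind: str, seed: int = 0) -> ModelBundle:
    """Untrained bundle with seeded uniform fan-in-scaled initialization."""
    spec = architecture_spec(kind)
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    for l in spec.layers:
        if l.op == "dense":
            bound = 1.0 / np.sqrt(l.fan_in)
            params[f"{l.name}.W"] = rng.uniform(-bound, bound, (l.fan_out, l.fan_in))
            params[f"{l.name}.b"] = rng.uniform(-bound, bound, l.fan_out)
        elif l.op == "conv":
            bound = 1.0 / np.sqrt(l.fan_in * l.kernel)
            params[f"{l.name}.W"] = rng.uniform(-bound, bound, (l.fan_out, l.fan_in, l.kernel))
            params[f"{l.name}.b"] = rng.uniform(-bound, bound, l.fan_out)
        elif l.op == "convtranspose":
            bound = 1.0 / np.sqrt(l.fan_in * l.kernel)
            params[f"{l.name}.W"] = rng.uniform(-bound, bound, (l.fan_in, l.fan_out, l.kernel))
            params[f"{l.name}.b"] = rng.uniform(-bound, bound, l.fan_out)
    bundle = ModelBundle(spec=spec, params=params, meta={"seed": seed})
    assert bundle.n_params() == count_parameters(spec)
    return bundle


# ---------------------------------------------------------------------------
# forward / backward


def forward(bundle: ModelBundle, x: np.ndarray, caches: list | None = None) -> np.ndarray:
    """Dive probabilities (N, 20) for a batch of windows (N, 3, 20).

    A single window (3, 20) is accepted and returns shape (20,). Pass a
    list as ``caches`` to retain intermediates for :func:`backward`.
    """
    single = x.ndim == 2
    x = np.asarray(x, dtype=float)
    if single:
        x = x[None]
    if x.shape[1:] != (bundle.spec.input_channels, bundle.spec.window_length):
        raise ValueError(f"expected windows of shape (3, {bundle.spec.window_length}), got {x.shape[1:]}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input window")
    p = bundle.params
    record = caches is not None

    def cache():
        c = {}
        if record:
            caches.append(c)
        return c

    if bundle.kind == "FCNET":
        h = x.reshape(len(x), -1)
        for l in bundle.spec.layers:
            c = cache()
            h = _dense_fwd(h, p[f"{l.name}.W"], p[f"{l.name}.b"], c)
            if l.activation == "relu":
                c["z"] = h
                h = _relu(h)
        out = _sigmoid(h)
    elif bundle.kind == "CNNET":
        h = x
        for l in bundle.spec.layers:
            c = cache()
            h = _conv_fwd(h, p[f"{l.name}.W"], p[f"{l.name}.b"], c)
            if l.activation == "relu":
                c["z"] = h
                h = _relu(h)
        out = _sigmoid(h[:, 0, :])
    else:  # UNET
        c1, c2 = cache(), cache()
        e = _relu_store(_conv_fwd(x, p["enc1.W"], p["enc1.b"], c1), c1)
        e = _relu_store(_conv_fwd(e, p["enc2.W"], p["enc2.b"], c2), c2)
        cp = cache()
        h = _maxpool2_fwd(e, cp)
        c3, c4 = cache(), cache()
        h = _relu_store(_conv_fwd(h, p["mid1.W"], p["mid1.b"], c3), c3)
        h = _relu_store(_conv_fwd(h, p["mid2.W"], p["mid2.b"], c4), c4)
        cu = cache()
        u = _convtranspose_fwd(h, p["up.W"], p["up.b"], cu)
        h = np.concatenate([u, e], axis=1)  # (N, 48, 20)
        c5, c6 = cache(), cache()
        h = _relu_store(_conv_fwd(h, p["dec1.W"], p["dec1.b"], c5), c5)
        h = _relu_store(_conv_fwd(h, p["dec2.W"], p["dec2.b"], c6), c6)
        ch = cache()
        h = _conv_fwd(h, p["head.W"], p["head.b"], ch)
        out = _sigmoid(h[:, 0, :])
    if record:
        caches.append({"p_out": out})
    return out[0] if single else out


def _relu_store(z, cache):
    cache["z"] = z
    return _relu(z)


def backward(bundle: ModelBundle, caches: list, gp: np.ndarray) -> dict[str, np.ndarray]:
    """Parameter gradients given d(loss)/d(probability) for the batch.

    ``caches`` must come from a ``forward`` call with recording enabled;
    ``gp`` has shape (N, 20).
    """
    p = bundle.params
    grads = bundle.zero_grads()
    out = caches[-1]["p_out"]
    g = gp * out * (1.0 - out)  # through the sigmoid head

    if bundle.kind == "FCNET":
        for i, l in enumerate(reversed(bundle.spec.layers)):
            c = caches[len(bundle.spec.layers) - 1 - i]
            g = _dense_bwd(g, p[f"{l.name}.W"], c, grads, l.name)
            prev = bundle.spec.layers[len(bundle.spec.layers) - 2 - i] if len(bundle.spec.layers) - 2 - i >= 0 else None
            if prev is not None and prev.activation == "relu":
                pc = caches[len(bundle.spec.layers) - 2 - i]
                g = g * (pc["z"] > 0)
    elif bundle.kind == "CNNET":
        g = g[:, None, :]
        layers = bundle.spec.layers
        for i in range(len(layers) - 1, -1, -1):
            l = layers[i]
            g = _conv_bwd(g, p[f"{l.name}.W"], caches[i], grads, l.name)
            if i > 0 and layers[i - 1].activation == "relu":
                g = g * (caches[i - 1]["z"] > 0)
    else:  # UNET
        c1, c2, cp, c3, c4, cu, c5, c6, ch = caches[:9]
        g = g[:, None, :]
        g = _conv_bwd(g, p["head.W"], ch, grads, "head")
        g = g * (c6["z"] > 0)
        g = _conv_bwd(g, p["dec2.W"], c6, grads, "dec2")
        g = g * (c5["z"] > 0)
        g = _conv_bwd(g, p["dec1.W"], c5, grads, "dec1")
        gu, ge_skip = g[:, :24, :], g[:, 24:, :]
        g = _convtranspose_bwd(gu, p["up.W"], cu, grads, "up")
        g = g * (c4["z"] > 0)
        g = _conv_bwd(g, p["mid2.W"], c4, grads, "mid2")
        g = g * (c3["z"] > 0)
        g = _conv_bwd(g, p["mid1.W"], c3, grads, "mid1")
        g = _maxpool2_bwd(g, cp)
        g = g + ge_skip
        g = g * (c2["z"] > 0)
        g = _conv_bwd(g, p["enc2.W"], c2, grads, "enc2")
        g = g * (c1["z"] > 0)
        g = _conv_bwd(g, p["enc1.W"], c1, grads, "enc1")
    return grads
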