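"""Dive-prediction metrics and spatial evaluation.

Pointwise metrics: exact ROC curve (ties grouped), AUC by the composite
trapezoidal rule (equal to tie-corrected pairwise concordance), unweighted
binary cross-entropy and the dive-class F-score at a threshold. Spatial
metric: weighted Gaussian kernel-density maps of the dive distribution on
a 0.01-degree grid with 0.25-degree bandwidth, compared to the map built
from true dive locations by mean squared error of the normalized
densities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .training import DiveProbSeries

GRID_STEP_DEG = 0.01
KDE_BANDWIDTH_DEG = 0.25


@dataclass
class RocCurve:
    thresholds: np.ndarray  # descending
    fpr: np.ndarray
    tpr: np.ndarray


@dataclass
class DensityGrid:
    """Normalized density on a regular lon/lat grid (cell centres)."""

    lon_edges: np.ndarray
    lat_edges: np.ndarray
    values: np.ndarray  # (n_lat, n_lon), >= 0, integrates to 1 over the grid

    @property
    def cell_area(self) -> float:
        return float((self.lon_edges[1] - self.lon_edges[0]) * (self.lat_edges[1] - self.lat_edges[0]))


def _scores_labels(p, y) -> tuple[np.ndarray, np.ndarray]:
    p = p.p if isinstance(p, DiveProbSeries) else np.asarray(p, dtype=float)
    y = np.asarray(y).astype(bool)
    if p.shape != y.shape:
        raise ValueError("scores and labels must have the same shape")
    return p, y


def roc_curve(p, y) -> RocCurve:
    """Exact ROC from sorted unique scores; tied scores form one point."""
    s, y = _scores_labels(p, y)
    npos = int(y.sum())
    nneg = int((~y).sum())
    if npos == 0 or nneg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-s, kind="stable")
    ss, yy = s[order], y[order]
    tp = np.cumsum(yy)
    fp = np.cumsum(~yy)
    last = np.concatenate((np.flatnonzero(np.diff(ss) != 0), [len(ss) - 1]))
    thresholds = np.concatenate(([np.inf], ss[last]))
    tpr = np.concatenate(([0.0], tp[last] / npos))
    fpr = np.concatenate(([0.0], fp[last] / nneg))
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr)


def auc(curve_or_p, y=None) -> float:
    """Area under the ROC curve by the composite trapezoidal rule."""
    curve = curve_or_p if isinstance(curve_or_p, RocCurve) else roc_curve(curve_or_p, y)
    return float(np.trapezoid(curve.tpr, curve.fpr))


def bce_metric(p, y) -> float:
    """Unweighted mean binary cross-entropy with 1e-7 clipping."""
    s, yb = _scores_labels(p, y)
    pc = np.clip(s, 1e-7, 1.0 - 1e-7)
    return float(np.mean(-(yb * np.log(pc) + (~yb) * np.log1p(-pc))))


def f_score(p, y, threshold: float = 0.5) -> float:
    """F-score of the dive class at a hard threshold (default 0.5)."""
    s, yb = _scores_labels(p, y)
    pred = s > threshold
    tp = int((pred & yb).sum())
    fp = int((pred & ~yb).sum())
    fn = int((~pred & yb).sum())
    if tp + fp == 0:
        warnings.warn("no predicted positives; F-score set to 0")
        return 0.0
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2.0 * precision * recall / (precision + recall)


def _grid_edges(vals: np.ndarray, step: float, pad: float) -> np.ndarray:
    lo = np.floor((vals.min() - pad) / step) * step
    hi = np.ceil((vals.max() + pad) / step) * step
    return np.arange(lo, hi + step / 2, step)


def kde_map(
    lon: np.ndarray,
    lat: np.ndarray,
    weights: np.ndarray,
    grid_step: float = GRID_STEP_DEG,
    bandwidth: float = KDE_BANDWIDTH_DEG,
    lon_edges: np.ndarray | None = None,
    lat_edges: np.ndarray | None = None,
) -> DensityGrid:
    """Weighted isotropic-Gaussian KDE in degree space.

    Evaluated at cell centres and renormalized to integrate to 1 over the
    grid (sum of value x cell area). The default grid spans the data plus
    three bandwidths. Weight scale is irrelevant (weights are normalized).
    """
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    w = np.asarray(weights, float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if w.sum() <= 0:
        raise ValueError("weights must not be all zero")
    if lon_edges is None:
        lon_edges = _grid_edges(lon, grid_step, 3 * bandwidth)
    if lat_edges is None:
        lat_edges = _grid_edges(lat, grid_step, 3 * bandwidth)
    cx = 0.5 * (lon_edges[:-1] + lon_edges[1:])
    cy = 0.5 * (lat_edges[:-1] + lat_edges[1:])
    # separable Gaussian: accumulate outer products per point
    wn = w / w.sum()
    dens = np.zeros((cy.size, cx.size))
    chunk = 512
    inv2s2 = 1.0 / (2.0 * bandwidth * bandwidth)
    for i in range(0, lon.size, chunk):
        gx = np.exp(-((cx[None, :] - lon[i : i + chunk, None]) ** 2) * inv2s2)
        gy = np.exp(-((cy[None, :] - lat[i : i + chunk, None]) ** 2) * inv2s2)
        dens += np.einsum("py,px->yx", gy * wn[i : i + chunk, None], gx, optimize=True)
    area = (lon_edges[1] - lon_edges[0]) * (lat_edges[1] - lat_edges[0])
    total = dens.sum() * area
    if total <= 0:
        raise ValueError("degenerate density (all mass outside the grid)")
    return DensityGrid(lon_edges=lon_edges, lat_edges=lat_edges, values=dens / total)


def map_mse(est: DensityGrid, ref: DensityGrid) -> float:
    """Mean squared difference of two density maps on the same grid."""
    if est.values.shape != ref.values.shape or not (
        np.allclose(est.lon_edges, ref.lon_edges) and np.allclose(est.lat_edges, ref.lat_edges)
    ):
        raise ValueError("density grids do not match")
    return float(np.mean((est.values - ref.values) ** 2))
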