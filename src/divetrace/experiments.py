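"""The three benchmark protocols, run end to end on simulated datasets.

(a) Training benchmark: per dataset x resolution (5/15/30 s) x model
    (FPT, HMM, FCNet, CNNet, UNet), split trips 50/30/20 into train/
    validation/test, fit, and report AUC / BCE / F-score on the test trips.
(b) Generalization: apply trained bundles to a different colony/species
    without weight updates (source normalization statistics reused), and
    additionally score the predicted dive-distribution map against the
    true-dive map by MSE.
(c) Fine-tuning ladder: for 1/5/15/30 training trips, train from scratch
    and fine-tuned from a pretrained bundle on the same (nested) trip
    subsets, and compare test AUC and epochs to early stopping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fpt import fpt_dive_probability
from .hmm import HmmSpec, hmm_dive_probability, hmm_fit, select_dive_state
from .evaluation import auc, bce_metric, f_score, kde_map, map_mse
from .features import fit_norm_stats, make_window_dataset
from .networks import build
from .preprocess import ANALYSIS_RESOLUTIONS, Trip, downsample, deployment_to_trip, split_dataset
from .simulate import preset_config, simulate_dataset
from .training import DiveProbSeries, TrainConfig, fine_tune, predict_trip, train

NETWORKS = ("FCNET", "CNNET", "UNET")
ALL_MODELS = ("FPT", "HMM") + NETWORKS
TRAIN_STRIDE = 10  # windows overlap by half during training; inference is stride 1


@dataclass
class ExperimentPlan:
    datasets: tuple[str, ...] = ("booby_pescadores",)
    resolutions: tuple[int, ...] = ANALYSIS_RESOLUTIONS
    models: tuple[str, ...] = ALL_MODELS
    n_trips: int = 30
    split_seed: int = 0
    train_seed: int = 0
    ladder: tuple[int, ...] = (1, 5, 15, 30)
    replicate_seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    max_epochs: int = 60
    patience: int = 3

    def __post_init__(self):
        if not self.datasets or not self.models:
            raise ValueError("plan needs at least one dataset and one model")
        unknown = set(m.upper() for m in self.models) - set(ALL_MODELS)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")


def make_dataset(species_tag: str, n_trips: int, seed: int) -> list[Trip]:
    """Simulate, degrade with gaps, interpolate and label a colony dataset."""
    cfg = preset_config(species_tag, seed)
    deps = simulate_dataset(cfg, n_trips, seed)
    return [deployment_to_trip(d) for d in deps]


def _subset(trips: list[Trip], ids) -> list[Trip]:
    ids = set(ids)
    return [t for t in trips if t.trip_id in ids]


def _concat_eval(series: list[DiveProbSeries], trips: list[Trip]):
    p = np.concatenate([s.p for s in series])
    y = np.concatenate([t.dive for t in trips])
    return p, y


def _fit_network(kind, train_trips, val_trips, cfg: TrainConfig, species_tag=""):
    norm = fit_norm_stats(train_trips, species_tag)
    tws = make_window_dataset(train_trips, norm, stride=TRAIN_STRIDE)
    vws = make_window_dataset(val_trips, norm, stride=TRAIN_STRIDE)
    bundle = build(kind, cfg.seed)
    bundle.norm_stats = norm
    return train(bundle, tws, vws, cfg)


def evaluate_model(
    model: str,
    train_trips: list[Trip],
    val_trips: list[Trip],
    test_trips: list[Trip],
    class_weight: float,
    seed: int,
    species_tag: str = "",
    max_epochs: int = 60,
    patience: int = 3,
) -> dict:
    """Fit one model (or run one baseline) and score it on the test trips."""
    model = model.upper()
    row = {"model": model, "auc": np.nan, "bce": np.nan, "f_score": np.nan,
           "train_loss": np.nan, "validation_loss": np.nan, "bundle": None}
    testable = [t for t in test_trips if len(t) >= 20]
    if model == "FPT":
        series = [fpt_dive_probability(t) for t in testable]
    elif model == "HMM":
        n_states = 4 if "cormorant" in species_tag else 3
        spec = hmm_fit(train_trips, n_states, seed=seed, restarts=3, max_iter=100)
        spec.dive_state_index = select_dive_state(spec, train_trips)
        series = [hmm_dive_probability(spec, t) for t in testable]
        row["bundle"] = spec
    else:
        cfg = TrainConfig(class_weight=class_weight, seed=seed, max_epochs=max_epochs, patience=patience)
        bundle, hist = _fit_network(model, train_trips, val_trips, cfg, species_tag)
        row["bundle"] = bundle
        row["train_loss"] = hist.train_loss[hist.best_epoch - 1]
        row["validation_loss"] = hist.validation_loss[hist.best_epoch - 1]
        series = [predict_trip(bundle, t) for t in testable]
    p, y = _concat_eval(series, testable)
    row["auc"] = auc(p, y)
    row["bce"] = bce_metric(p, y)
    row["f_score"] = f_score(p, y)
    return row


def run_training_benchmark(plan: ExperimentPlan, return_bundles: bool = False):
    """Protocol (a): the dataset x resolution x model benchmark table."""
    rows = []
    bundles = {}
    for tag in plan.datasets:
        cfg = preset_config(tag, plan.split_seed)
        trips_1s = make_dataset(tag, plan.n_trips, plan.split_seed)
        split = split_dataset([t.trip_id for t in trips_1s], seed=plan.split_seed)
        for dt in plan.resolutions:
            trips = [downsample(t, dt) for t in trips_1s]
            tr = _subset(trips, split.train)
            va = _subset(trips, split.validation)
            te = _subset(trips, split.test)
            for model in plan.models:
                row = evaluate_model(
                    model, tr, va, te, cfg.class_weight, plan.train_seed, tag,
                    plan.max_epochs, plan.patience,
                )
                bundle = row.pop("bundle")
                name = f"{tag}_{model}_{dt}s"
                if bundle is not None:
                    bundles[name] = bundle
                rows.append(
                    dict(dataset=tag, resolution=dt, reference_name=name,
                         split_seed=plan.split_seed, train_seed=plan.train_seed, **row)
                )
    table = pd.DataFrame(rows)
    return (table, bundles) if return_bundles else table


def run_generalization(
    bundles: dict,
    target_trips: list[Trip],
    target_dt: int,
    train_trips_for_hmm: list[Trip] | None = None,
) -> pd.DataFrame:
    """Protocol (b): apply trained bundles to an unseen dataset.

    No weight updates; network bundles keep their source normalization
    statistics. Adds the KDE dive-map MSE against the true-dive map.
    """
    testable = [t for t in target_trips if len(t) >= 20]
    lon = np.concatenate([t.lon for t in testable])
    lat = np.concatenate([t.lat for t in testable])
    y = np.concatenate([t.dive for t in testable])
    ref = kde_map(lon, lat, y.astype(float))
    rows = []
    for name, bundle in bundles.items():
        if isinstance(bundle, HmmSpec):
            series = [hmm_dive_probability(bundle, t, train_trips_for_hmm) for t in testable]
        else:
            if bundle.spec.window_length != 20:
                raise ValueError("unexpected window length")
            bdt = bundle.meta.get("dt")
            if bdt is not None and bdt != target_dt:
                raise ValueError(f"model resolution {bdt}s does not match target {target_dt}s")
            series = [predict_trip(bundle, t) for t in testable]
        p, _ = _concat_eval(series, testable)
        est = kde_map(lon, lat, p, lon_edges=ref.lon_edges, lat_edges=ref.lat_edges)
        rows.append(
            dict(model=name, auc=auc(p, y), bce=bce_metric(p, y),
                 f_score=f_score(p, y), map_mse=map_mse(est, ref))
        )
    return pd.DataFrame(rows)


def run_finetuning_ladder(
    pretrained,
    target_trips: list[Trip],
    class_weight: float,
    ladder: tuple[int, ...] = (1, 5, 15, 30),
    replicate_seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
    val_trips: list[Trip] | None = None,
    test_trips: list[Trip] | None = None,
    max_epochs: int = 60,
    patience: int = 3,
) -> pd.DataFrame:
    """Protocol (c): scratch vs fine-tuned at several training-set sizes.

    ``target_trips`` is the training pool; subsets are nested across
    ladder sizes within a seed. Validation and test trips are fixed.
    """
    if val_trips is None or test_trips is None:
        raise ValueError("validation and test trips must be provided")
    if max(ladder) > len(target_trips):
        raise ValueError(f"need at least {max(ladder)} training trips, have {len(target_trips)}")
    testable = [t for t in test_trips if len(t) >= 20]
    rows = []
    for seed in replicate_seeds:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(target_trips))
        for n in ladder:
            subset = [target_trips[i] for i in order[:n]]
            norm = fit_norm_stats(subset)
            tws = make_window_dataset(subset, norm, stride=TRAIN_STRIDE)
            vws = make_window_dataset(val_trips, norm, stride=TRAIN_STRIDE)
            if len(tws) == 0:
                continue
            cfg = TrainConfig(class_weight=class_weight, seed=seed,
                              max_epochs=max_epochs, patience=patience)
            for init in ("scratch", "finetune"):
                if init == "scratch":
                    bundle = build(pretrained.kind, seed)
                    bundle.norm_stats = norm
                    fitted, hist = train(bundle, tws, vws, cfg)
                else:
                    fitted, hist = fine_tune(pretrained, tws, vws, cfg, norm_stats=norm)
                series = [predict_trip(fitted, t) for t in testable]
                p, y = _concat_eval(series, testable)
                rows.append(
                    dict(init=init, n_trips=n, seed=seed, auc=auc(p, y),
                         epochs=hist.stopped_epoch, best_epoch=hist.best_epoch)
                )
    return pd.DataFrame(rows)
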