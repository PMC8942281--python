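# divetrace

Inferring seabird dives from GPS-only trajectories.

Seabird foraging trips are routinely recorded with GPS loggers, but the
behaviour of interest — diving for prey — is only directly observed when a
pressure sensor (time-depth recorder, TDR) is deployed alongside. Many
historical datasets are GPS-only. `divetrace` benchmarks methods that
recover the per-position dive/no-dive state from the trajectory alone:

* three window-based neural segmentation architectures — a multilayer
  perceptron (**FCNet**, ~568k parameters), a fully convolutional network
  (**CNNet**, ~5k parameters) and a one-level 1-D **U-Net** (~20k
  parameters) — each mapping a 3-channel window of 20 consecutive
  positions (step speed, turning angle, coverage ratio) to 20 per-position
  dive probabilities through a sigmoid head;
* two classical baselines: **first-passage time** (FPT; the time to cross
  a circle of radius r, with r chosen to maximize the variance of log
  passage times, min-max normalized to a probability) and a **hidden
  Markov model** with gamma step lengths and von Mises turning angles
  (3 states for booby-like, 4 for cormorant-like data), whose dive
  probability is the forward-backward posterior of the dive state.

Training uses weighted binary cross-entropy (dives are 0.2–9.4% of
positions; weight 30 for booby-like and 5 for cormorant-like datasets),
Adam at learning rate 0.001, and early stopping on validation loss. A
whole trip is scored by averaging, per position, the probabilities of all
stride-1 windows covering it. Evaluation reports ROC/AUC (composite
trapezoidal rule), binary cross-entropy and F-score, plus a spatial
metric: mean squared error between weighted kernel-density dive maps
(0.01° grid, 0.25° bandwidth) and the map built from true dive locations.

Because the field datasets behind the original study are not public, the
package ships a calibrated multi-state movement simulator
(`divetrace.simulate`): a four-state behavioural chain (travel, search,
dive, rest) at 1-s resolution whose stationary statistics are solved in
closed form to match published per-species summaries — dive fraction,
dive duration, GPS gap fraction, surface-resting fraction and trip
duration — for four tropical-seabird colony datasets (Peruvian boobies
and Guanay cormorants from Pescadores, Peruvian boobies from Guañape,
masked boobies from Fernando de Noronha). All experiments run end to end
on this simulator; see `docs/methods.md` for what that does and does not
demonstrate about field data.

The networks, backpropagation and Adam are implemented in numpy with
explicit forward/backward passes (gradients are verified against finite
differences in the test suite), so the package has no deep-learning
framework dependency.

## Worked example

```python
import numpy as np
from divetrace.experiments import ExperimentPlan, run_training_benchmark

plan = ExperimentPlan(
    datasets=("booby_pescadores",),
    resolutions=(5, 15, 30),
    models=("FPT", "CNNET", "UNET"),
    n_trips=30, split_seed=1, train_seed=1,
)
table = run_training_benchmark(plan)
print(table[["resolution", "model", "auc", "bce", "f_score"]].round(3))
```

This simulates 30 booby-like foraging trips (1.3% dive seconds, 2.2% GPS
gaps), splits them 50/30/20 into train/validation/test at trip level,
fits each model at each resolution and scores the held-out trips:

```
 resolution model   auc   bce  f_score
          5   FPT 0.776 0.248    0.044
          5  UNET 0.913 0.393    0.182
          5 CNNET 0.916 0.390    0.182
         15   FPT 0.818 0.372    0.023
         15  UNET 0.899 0.574    0.339
         15 CNNET 0.900 0.558    0.366
         30   FPT 0.715 0.585    0.047
         30  UNET 0.883 0.829    0.386
         30 CNNET 0.887 0.776    0.436
```

AUC is the threshold-free probability that a random dive position is
ranked above a random non-dive position: the convolutional models
separate dives from travel/search/rest at 0.88–0.92 and beat the FPT
baseline in every cell, and performance degrades as the sampling interval
coarsens — the same qualitative ordering reported for the field datasets.
F-scores are low at the default 0.5 threshold because dive probabilities
are window means over a 1–3% positive class; AUC is the headline metric.

A command-line interface mirrors the pipeline:

```sh
divetrace simulate --species booby_pescadores --trips 10 --seed 1 --out data/
divetrace preprocess --gps data/ --colony -77.265,-11.775 --dt 15 --out trips/
divetrace train --arch unet --data trips/ --weight 30 --seed 1 --out model.ckpt
divetrace predict --model model.ckpt --trip trips/<trip>.csv --out probs.csv
```

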