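# Methods

## Problem

Given a GPS track of a foraging seabird sampled at a regular interval dt,
label every position as dive or no-dive. Supervision comes from a
co-deployed time-depth recorder (TDR): a position is a true dive when the
matched depth exceeds 2 m (strictly). The task is a 1-D segmentation
problem with heavy class imbalance (0.2–9.4% positive, species-dependent).

## Preprocessing

Raw GPS streams are cut into foraging trips — maximal runs of fixes
further than `min_distance` (default 1,000 m) from the colony lasting at
least `min_duration` (default 600 s); neither threshold is part of the
published protocol, so both are configurable and the defaults are chosen
to exclude colony loitering. Trips are linearly interpolated to the 1-s
TDR resolution; the `observed` mask records which seconds hold a real fix
and the coverage ratio of a resampled position is the fraction of
expected fixes actually recorded in its dt-second interval (the temporal
window of that ratio is a design choice here — the resampling interval
itself). Depth is matched to each second by nearest neighbour within
±0.5 s. Downsampling to the analysis resolutions (5/15/30 s) decimates
coordinates (every dt-th position, mimicking a lower-rate GPS rather than
averaging) and ORs the dive labels over each window: a window containing
at least one dive second is a dive. Train/validation/test splitting
(50/30/20) is at trip level to prevent window-level leakage between sets.

## Features and windows

Three channels per position: step speed (haversine distance of the
incoming step over dt, on a 6,371-km sphere), signed turning angle
(difference of consecutive great-circle bearings, wrapped to (-pi, pi]
with about-turns mapped to +pi; left turns positive), and the coverage
ratio. The networks consume windows of L = 20 positions at every
resolution (so a window spans 100 s at dt = 5 and 600 s at dt = 30): the
fixed network input size requires a constant position count. Speed is
z-scored with statistics fitted on the training split only, the angle is
scaled by 1/pi, coverage is already in [0, 1]. Training windows use
stride L/2 = 10 for data economy; inference always uses stride 1 because
whole-trip probabilities are window means (below).

## Architectures

All three map a 3x20 window to 20 probabilities via a per-position
sigmoid head (the output has the same temporal resolution as the input):

* FCNet: flatten -> 100 -> 500 -> 500 -> 500 -> 20, ReLU between hidden
  layers; 567,620 parameters.
* CNNet: 1-D convolutions with 'same' zero padding,
  3->16 (k3) -> 16->32 (k3) -> 32->32 (k3) -> 32->1 (k1), ReLU then
  sigmoid; 4,865 parameters.
* UNet: encoder 3->24->24 (k3), max-pool 2 (20 -> 10), bottleneck
  24->48->48 (k3), transposed-conv upsample 48->24 (k2 stride 2,
  10 -> 20), concatenation with the encoder output (48 channels), decoder
  48->24->24 (k3), head 24->1 (k1); 20,041 parameters.

The channel widths are fixed so the totals land on the advertised budgets
of ~5k (CNNet) and ~20k (UNet) after rounding; FCNet's per-position head
makes its total 567,620 rather than a round 500k. Layers are implemented
in numpy (float64) with explicit backward passes; the test suite checks
every architecture's gradients against central finite differences at
1e-4 relative tolerance. Initialization is uniform with fan-in scaling,
fully seeded.

## Training

Weighted binary cross-entropy, mean over all window positions of
-[w·y·ln p + (1-y)·ln(1-p)] with probabilities clipped to
[1e-7, 1-1e-7]; w = 30 for booby-like and 5 for cormorant-like datasets
(any positive value accepted). Adam (beta1 0.9, beta2 0.999, eps 1e-8) at
a fixed learning rate of 0.001, batch size 64, seeded shuffling. Early
stopping halts training once the validation loss has not improved for
`patience` epochs (default 1 in the library, 3 in the benchmark driver to
smooth mini-batch noise on small simulated datasets); the weights of the
best-validation epoch are restored. Batch size and the 100-epoch cap are
implementation choices sized for minutes-scale CPU runs. Fine-tuning is
the same procedure initialized from a pretrained bundle with all layers
unfrozen and normalization statistics refitted on the new training trips.
Whole-trip prediction averages, per position, the probabilities of every
stride-1 window containing it; window means are applied at inference
only, not inside the training loss.

## Baselines

**FPT.** The first-passage time at a position sums a forward and a
backward first exit from the circle of radius r centred there, each
linearly interpolated between the bracketing fixes and truncated at the
trip boundary when the circle is never exited. The analysis radius
maximizes the variance of log passage times (the log follows the method's
originating literature; a flag switches to raw variance) over 20
log-spaced candidates spanning the 1st percentile of step lengths to 100x
the 99th percentile. Passage times become probabilities by per-trip
min-max normalization (per trip because the passage-time scale drifts
between trips); constant passage times degrade to 0.5 with a warning.

**HMM.** Steps (gamma, floored at 1 mm; zero-length steps get angle 0)
and turning angles (von Mises) per state, 3 states for booby-like and 4
for cormorant-like data. Baum-Welch EM with exact weighted MLE M-steps:
the gamma shape solves ln k - psi(k) = ln(mean) - mean-log by bracketed
root finding, the von Mises concentration solves I1/I0(k) = R likewise,
so the log-likelihood is non-decreasing per iteration (verified in
tests). Initialization seeds state means from a k-quantile split of the
pooled step lengths with near-diagonal transitions; restarts perturb the
init multiplicatively and the best log-likelihood wins. Convergence at
Δlog-lik < 1e-6 or 500 iterations. The dive state is chosen supervised —
the state whose posterior best ranks the training labels (pairwise
concordance) — falling back to the smallest-mean-step state when no
labels are available.

## Evaluation

Exact ROC from sorted unique scores with ties grouped; AUC by the
composite trapezoidal rule (equal to tie-corrected pairwise concordance,
checked against a brute-force oracle at 1e-9). The reported BCE is
unweighted — the class weight is a fitting device, not part of the
metric; a parameter switches this. F-score uses a 0.5 threshold by
default. Dive maps are weighted isotropic-Gaussian KDEs computed in
degree space (0.01° cells, 0.25° bandwidth, no geodesic correction),
renormalized to integrate to 1 over the grid before the MSE comparison so
the MSE is scale-free; its absolute magnitude is therefore not comparable
to map-error numbers computed on unnormalized densities.

## Simulator

The generator stands in for the four field datasets. A four-state
behavioural chain (TRAVEL, SEARCH, DIVE, REST) steps at 1 s with the
foraging structure TRAVEL -> {SEARCH, REST}, SEARCH -> {TRAVEL, DIVE},
DIVE -> SEARCH, REST -> TRAVEL: dives occur only inside
area-restricted-search bouts, which is what gives trajectory context its
predictive value. Given per-state mean dwell times and the published
dive and resting fractions, the transition matrix is solved in closed
form from stationary flow balance (the TRAVEL:SEARCH occupancy split is
the unique feasible value). Dwell means: travel 120 s (60 s for the
heavy-resting cormorant and masked-booby presets, which alternate travel
and surface rest), search 20 s, dive = the published mean dive duration
(dwells are geometric, so the mean matches exactly and the spread
approximately), rest 60 s. The REST occupancy target is debited by one
second per dive bout because the first post-dive displacement carries the
dive's slow speed with a non-dive label, which the speed-based resting
statistic counts as resting.

Per-state speeds are gamma (travel 11±2.5 m/s, search 4±1, dive
0.35±0.2, rest 0.3±0.2 — rest sits below the 1 m/s resting threshold)
clipped at 29.9 m/s; headings integrate von Mises turns (travel kappa 25,
search 1, dive 0.5, rest 0.2). Depth during a dive bout is a half-sine
from a 2.5-m floor to a peak sampled uniformly per species (boobies
2.5–8 m, cormorants 2.5–30 m), so the 2-m threshold crossing coincides
exactly with the behavioural state. GPS gaps are deleted in contiguous
runs with geometric lengths (mean 10 s) until exactly round(fraction x n)
fixes are gone, endpoints pinned — gaps in the field come from
submersion and are bursty, not i.i.d. Trip durations are normal with the
published mean/sd in minutes, floored at 10 min.

What the simulator does not emulate: environmental forcing, prey-field
structure beyond the ARS bouts, central-place attraction (trips start at
the colony but do not return), device-specific GPS error, or multi-animal
interaction. Passing benchmarks on this generator therefore demonstrates
that the implementations are correct and that the methods rank as
expected when dives are embedded in search bouts; it does not reproduce
the published field-data metrics, whose datasets are not deposited.

## Benchmark problem sizes

The shipped benchmark simulates 30 trips per dataset (split 15/9/6),
trains for at most 60 epochs with patience 3, and runs at all three
resolutions; the fine-tuning comparison pretrains a CNNet on 20
cormorant-like trips at 15 s and runs 10 paired scratch/fine-tune
replicates on 5 masked-booby-like trips. Simulator calibration is
checked over 1.2M simulated seconds per preset (4.8M for the
heavy-resting presets, whose minute-scale rest bouts make the resting
fraction the slowest-mixing statistic). These sizes were chosen so the
full suite runs in CPU-minutes while keeping Monte-Carlo error well
inside the asserted tolerances.

## Known limitations

* The HMM is fitted per resolution without covariates or zero-inflation
  and makes no attempt at numerical parity with reference R
  implementations; it is a baseline, not a product.
* F-scores at the fixed 0.5 threshold are pessimistic for rare-dive
  datasets because window-mean probabilities are diluted; AUC is the
  primary metric.
* KDE maps ignore the metric distortion of degree space away from the
  equator (consistent with the stated grid/bandwidth units).
* At 30-s resolution a 2.5-s dive changes a single 30-s displacement
  only slightly; the achievable AUC on booby-like data drops accordingly,
  mirroring the resolution sensitivity of the original study.
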