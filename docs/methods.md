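# Methods

This document records the model, the numerical choices, and the
statistical rules the package uses, including the calibration behind the
built-in parameter-line presets and synthetic-data operating points.

## Model

The three-variable Hindmarsh–Rose neuron:

```
dx/dt = y − a·x³ + b·x² − z + I
dy/dt = c − d·x² − y
dz/dt = r·( s·(x − x_rest) − z )
```

with the standard constants a = 1, b = 3, c = 1, d = 5, s = 4,
x_rest = −1.6. The control parameters are the injected current `I` and
the slow time-scale `r`. `x` is the membrane potential; spikes are `x`
maxima above a threshold (default 0.0) separated by a refractory
minimum distance.

Optional channel noise is added to the `dy` equation as an
Euler–Maruyama term `σ·√dt·ξ` with `ξ ~ N(0, 1)` per step
(`HRParams.noise_intensity = σ`).

## Numerics

- Fixed-step classical Runge–Kutta (RK4), `dt = 0.01` by default. The
  integration kernels are numba-compiled; results are bitwise
  reproducible for a given seed.
- Spike times are refined by quadratic interpolation through the three
  samples around each local maximum, so ISIs are accurate to well below
  `dt`.
- The largest Lyapunov exponent (LLE) uses the Benettin method on the
  linearized (tangent) flow with periodic renormalization: transient
  `t = 500`, averaging window `t = 5000` by default. Sanity anchors:
  the chaotic point (I = 2.53, r = 0.0245) gives LLE ≈ +0.007, periodic
  points give |LLE| < 0.002, quiescent points give LLE < 0.

## Regime classification

**Period of an ISI series.** `classify_period` returns the smallest
k ≤ 8 such that `max |v[k:] − v[:−k]| < rel_tol · mean(v)`; otherwise
the series is aperiodic. Default `rel_tol` is 0.01 for noiseless data
and 0.05 where jitter is expected. Because the criterion uses the
*maximum* deviation, it is deliberately strict: a single outlying ISI
(e.g. one long interval hit by multiplicative jitter) can veto a
period, which matters when choosing jitter levels for synthetic data
(see below).

**Point classification.** `classify_point` simulates a post-transient
ISI series and applies `classify_period`; aperiodic series are promoted
to "chaotic" only when the LLE at that point is positive, and short or
empty spike trains yield "quiescent". Points with parameter noise are
refused — classification is defined for the deterministic flow.

**Segmentation of nonstationary records.** `segment_scenario` slides a
window over the ISI series, classifies each window, and merges
consecutive windows with equal labels into segments.

## Chaotic regions in the (I, r) plane

`compute_lle_map` evaluates the LLE on a regular grid over the
rectangle `2.3 ≤ I ≤ 3.42`, `0.001 ≤ r ≤ 0.035`.
`label_chaotic_regions` thresholds the map at LLE > 0.002, labels
connected components, and drops components smaller than `min_cells = 4`.
At moderate grid resolution (56 × 35 and above) exactly two regions
survive: a small island inside the period-1/period-2 transition zone
containing (2.53, 0.0245), and a large comb-shaped region toward higher
I and lower r.

Connectivity is 8-neighbor (`connectivity=2`) by default: the comb
region's teeth are thin and diagonal at coarse resolution, and
4-neighbor labeling fragments them into artifact components. 4-neighbor
labeling remains available via `connectivity=1`.

## Line presets

The ten presets in `hrchaos/data/line_presets.json` were calibrated
numerically against LLE maps and 150-point scans. Their verified regime
orders (at 150 points, default scan settings) include:

- `BL1`: period-1 → chaotic → period-2 → period-1 (the basic crossing
  of the chaotic band).
- `BL2`: period-1 → chaotic → period-2 → period-4 → chaotic → period-3.
- `SL1`: the full symmetric cascade period-1 → chaotic → period-2 →
  period-4 → period-8 → chaotic → period-8 → period-4 → period-2 →
  period-1.
- `TL1`/`TL2`: period-doubling ladders 2 → 4 → 8 (→ chaos).
- `TL4`: a period-adding staircase 2 → 4 → 2 → 3 → 4 → 5.
- `ML0`: a vertical cut at I = 2.5 showing period-1 → chaos → period-2
  followed by the adding staircase.

## Nonlinear prediction error (NPE)

The NPE asks whether an irregular ISI series is short-term predictable.
The series is delay-embedded in dimension m = 4; each embedded point is
predicted h steps ahead by the mean of the futures of its
k = max(1, round(eps·P)) nearest neighbors (eps = 0.01 of the P valid
points; self-matches excluded; ties broken by stable index order). The
RMS prediction error is normalized by the error of the constant
mean-predictor, so NPE = 0 is perfect prediction and NPE = 1 is
no skill.

Surrogate testing (`npe_test`) compares the original NPE against 10
random shuffles of the series over h = 1..10. The series is flagged
deterministic at step h when its NPE lies more than 3 surrogate standard
deviations below the surrogate mean.

**No-skill level of the estimator.** For an i.i.d. series the k-neighbor
mean predictor has expected NPE `√(1 + 1/k)`, not exactly 1: with
k = 5 (≈ 500 ISIs) surrogates hover near 1.10, with k = 10 (≈ 1000
ISIs) near 1.05. Analyses that require the surrogate mean to sit within
0.1 of 1.0 should therefore use ≥ 1000 ISIs; the unit tests verify the
√(1 + 1/k) level directly.

Reference behavior at the chaotic point (2.53, 0.0245): NPE(h=1) ≈ 0.6,
well separated from the surrogate band, with NPE rising toward the
no-skill level as h grows.

## Synthetic data

All generators are seeded and deterministic per seed; every record
carries ground truth. ISI-level measurement noise is multiplicative
jitter with coefficient of variation `isi_jitter_cv` (default 0.005),
optionally followed by quantization to a sampling grid.

**Stochastic alternation** (`gen_stochastic_alternation`) sits the
neuron at a period-adding boundary with channel noise so the record
mixes the two adjacent patterns. Two calibrated operating points:

- (I = 2.492, r = 0.0049) with σ = 0.05 — a bursting-mode boundary
  where 3-spike and 4-spike bursts alternate irregularly (bimodal burst
  sizes). Note the *deterministic skeleton* of bursting keeps the NPE
  low here at any noise level: within-burst ISIs remain predictable.
- (I = 3.5667, r = 0.02) with σ = 0.01 and jitter cv = 0.1 — a tonic
  period-1/period-2 boundary where the pattern contrast is smaller than
  the jitter, producing a record the NPE surrogate test correctly does
  *not* flag as deterministic.

If the noise is too small to actually mix patterns, the generator warns
and labels the record periodic rather than emitting a false
"stochastic" truth.

**Washout drift** (`gen_washout`) sweeps (I, r) slowly along a line
while integrating, producing a nonstationary record whose truth
segments come from a stationary pre-scan of the line. Slow passage
through bifurcations constrains which drifts are recoverable by
windowed segmentation:

- Crossing a period-doubling under drift is *delayed*: the subharmonic
  splitting stays microscopic long past the static threshold, so the
  record never shows the new period where the truth says it should.
- Crossing a period-adding boundary produces a hesitation stretch
  mixing both patterns, comparable to a segmentation window in length.
- Entering/leaving chaos blends gracefully: the transition is absorbed
  into the chaotic segment.

The calibrated recoverable drift therefore routes period-1 → chaos →
period-2 along the long axis of the chaotic band, from (2.40, 0.0284)
to (2.62, 0.0189). With duration 2·10⁵, jitter cv = 0.002 and
segmentation window 400, the recovered label order matches the truth
exactly and boundaries land within one window. The small jitter matters
because the max-based period criterion is sensitive to outliers on long
burst-period ISIs.

## Limitations

- Fixed-step RK4 with dt = 0.01 is tuned for this model's time scales;
  it is not adaptive and will not flag slow accuracy loss at extreme
  parameters (outright divergence raises an error).
- Period detection is capped at k = 8; longer periodic patterns are
  reported as aperiodic.
- The LLE-map region count depends on grid resolution below ~56 × 35
  cells; coarser maps can merge or drop thin structures.
- NPE surrogate comparisons assume ≥ ~500 ISIs; the estimator's
  √(1 + 1/k) bias makes shorter series look "worse than chance".
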