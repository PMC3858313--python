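# hrchaos

Tools for simulating and analyzing chaotic spiking in the
Hindmarsh–Rose neuron model, focused on the narrow chaotic band that
separates the period-1 and period-2 firing regimes in the
(I, r) parameter plane — where I is the injected current and r the
slow-variable time-scale parameter.

The package provides:

- **`hr_model`** — the three-variable Hindmarsh–Rose equations, a fixed-step
  RK4 integrator (with optional Euler–Maruyama channel noise), spike
  detection, ISI extraction, and a Benettin-style largest Lyapunov
  exponent (LLE).
- **`regimes`** — ISI-based period classification (period-k up to k = 8,
  aperiodic, stochastic, quiescent), point classification combining ISI
  patterns with LLE evidence, and sliding-window segmentation of
  nonstationary records.
- **`parameter_space`** — parameter lines and scans through the (I, r)
  plane, scenario extraction (ordered regime sequences), LLE maps over a
  rectangle, and connected-component labeling of chaotic regions. Ten
  calibrated line presets cross the chaotic band in different ways.
- **`isi_analysis`** — first-return maps, delay embedding, and the
  nonlinear prediction error (NPE) with shuffled-surrogate testing to
  distinguish deterministic (chaotic) irregularity from stochastic
  irregularity.
- **`synthetic_data`** — labeled synthetic ISI records: stationary
  firing, noise-induced alternation between adjacent burst patterns, and
  slow parameter "washout" drifts, each with ground truth attached.
- **`hrchaos.cli`** — a thin command-line interface over the above.

See `docs/methods.md` for the model equations, numerical choices and
classification rules, and `examples/` for short narrative scripts.

## Quickstart

```python
from hrchaos import HRParams, largest_lyapunov, simulate_isis
from hrchaos.isi_analysis import EmbeddingConfig, npe_test

# the chaotic point between the period-1 and period-2 regimes
params = HRParams(I=2.53, r=0.0245)
print(largest_lyapunov(params))          # ~ +0.007  (positive: chaos)

isis = simulate_isis(params, n_isis=600, t_end=40000.0)
res = npe_test(isis, EmbeddingConfig(seed=0))
print(res.npe_original[0])               # ~ 0.58  (predictable)
print(res.npe_surrogate_mean[0])         # ~ 1.08  (surrogates are not)
print(res.deterministic_at(1))           # True
```

Scanning a parameter line and reading off the regime sequence:

```python
from hrchaos.parameter_space import LINE_PRESETS, ScanConfig, extract_scenario, scan_line

diagram = scan_line(LINE_PRESETS["BL1"], ScanConfig())
print([str(s.label) for s in extract_scenario(diagram)])
# ['period-1', 'chaotic', 'period-2', 'period-1']
```

## Command line

```sh
hrchaos simulate --I 2.53 --r 0.0245 --t-end 20000 --out isis.txt
hrchaos classify isis.txt --out label.json
hrchaos npe isis.txt --out-prefix npe
hrchaos return-map isis.txt --out rm.csv
hrchaos scan --preset BL1 --out-prefix bl1
hrchaos synth --kind stationary --I 2.53 --r 0.018 --n-isis 300 --out-prefix synth
```

Every command writes provenance (parameters, seed, package version)
alongside its outputs; `hrchaos --help` lists all options.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes fast unit tests against hand-computed and brute-force
oracles plus slower end-to-end tests (full LLE maps and 150-point line
scans). `scripts/acceptance.py --seed 0 --out report.json` computes the
headline surrogate-test numbers on a fresh simulation.
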