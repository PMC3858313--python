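"""Generate labeled synthetic ISI records for testing analysis pipelines.

Three generators, each returning a record plus its ground truth:
stationary firing at a fixed parameter point, noise-induced alternation
between two adjacent burst patterns, and a slow "washout" drift through
the chaotic band that takes the neuron from period-1 to period-2.
"""

from hrchaos import HRParams
from hrchaos.parameter_space import ParameterLine
from hrchaos.synthetic_data import (
    SyntheticSpec, gen_stationary, gen_stochastic_alternation, gen_washout)

series, truth = gen_stationary(
    SyntheticSpec(base_params=HRParams(I=2.53, r=0.018), seed=1), n_isis=200)
print(f"stationary: {len(series)} ISIs, truth = {truth}")

series, truth = gen_stochastic_alternation(
    SyntheticSpec(base_params=HRParams(I=2.492, r=0.0049,
                                       noise_intensity=0.05), seed=1),
    n_isis=200)
print(f"alternation: {len(series)} ISIs, truth = {truth}")

line = ParameterLine("wash", (2.40, 0.0284), (2.62, 0.0189), n_points=20)
series, truth = gen_washout(
    SyntheticSpec(drift_line=line, duration=30000.0, seed=1),
    prescan_points=20)
print(f"washout: {len(series)} ISIs")
for seg in truth:
    print(f"  {str(seg.label):9s}  ISIs {seg.start_index}..{seg.end_index}")
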