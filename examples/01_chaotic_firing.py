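"""A chaotic firing pattern wedged between two periodic ones.

At I = 2.53 the neuron fires a period-1 rhythm for r = 0.031, a
period-2 rhythm for r = 0.018, and an aperiodic, positive-Lyapunov
pattern in between at r = 0.0245.  This script simulates all three and
summarizes each with its ISI statistics, first-return-map structure and
largest Lyapunov exponent.
"""

from hrchaos import HRParams, largest_lyapunov, simulate_isis
from hrchaos.isi_analysis import first_return_map
from hrchaos.regimes import classify_period

for name, r in [("period-1", 0.031), ("chaotic", 0.0245), ("period-2", 0.018)]:
    params = HRParams(I=2.53, r=r)
    isis = simulate_isis(params, n_isis=300, t_end=20000.0)
    lle = largest_lyapunov(params)
    period = classify_period(isis.isis[-150:])
    points = first_return_map(isis.isis[-150:]).distinct_points(decimals=0)
    print(f"{name:9s} (r={r}):  period={period}  "
          f"return-map clusters={points:3d}  LLE={lle:+.4f}")
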