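"""Walk a line through the (I, r) parameter plane and read off regimes.

The BL1 preset crosses the narrow chaotic band that separates the
period-1 region from the period-2 region: the regime order along it is
period-1 -> chaotic -> period-2 -> period-1.  The chaotic band is only
a few percent of the line's length, so the scan needs a reasonably fine
step (100 points here; the presets default to 150) to resolve it.
"""

from hrchaos.parameter_space import (
    LINE_PRESETS, ParameterLine, ScanConfig, extract_scenario, scan_line)

preset = LINE_PRESETS["BL1"]
line = ParameterLine(preset.name, preset.start, preset.end, n_points=100)
diagram = scan_line(line, ScanConfig())

for step in extract_scenario(diagram):
    (I0, r0), (I1, r1) = step.start_point, step.end_point
    print(f"{str(step.label):10s}  from (I={I0:.3f}, r={r0:.4f}) "
          f"to (I={I1:.3f}, r={r1:.4f})  "
          f"[{step.end_index - step.start_index} scan points]")
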