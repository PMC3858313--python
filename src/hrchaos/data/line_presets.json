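{
  "provenance": "Endpoints were calibrated numerically against a 56x35 largest-Lyapunov-exponent map and 150-point regime scans of the rectangle 2.3 <= I <= 3.42, 0.001 <= r <= 0.035 (fixed-step RK4, dt = 0.01, transient 500, 120 ISIs per point, Benettin averaging time 5000).  Each entry records the regime sequence a default 150-point scan traverses, verified by scan_line + extract_scenario.  Coordinates are [I, r].",
  "lines": {
    "ML0": {
      "start": [2.5, 0.035],
      "end": [2.5, 0.001],
      "description": "Vertical reference cut at fixed I = 2.5 through the narrow chaotic region: period-1 -> chaotic -> period-2, then a period-adding staircase (3, 4, 5, 6, 8) toward small r."
    },
    "BL1": {
      "start": [2.38, 0.027],
      "end": [3.7, 0.016],
      "description": "Shallow oblique cut that crosses only the narrow chaotic region and returns to period-1 spiking at high I: period-1 -> chaotic -> period-2 -> period-1."
    },
    "BL2": {
      "start": [2.42, 0.03],
      "end": [2.85, 0.01],
      "description": "Oblique cut from the narrow chaotic region into the comb-shaped one: period-1 -> chaotic -> period-2 -> period-4 -> chaotic -> period-3."
    },
    "BL3": {
      "start": [2.42, 0.03],
      "end": [2.95, 0.006],
      "description": "Deeper oblique cut traversing both chaotic regions and the period-adding ladder: contains period-2 -> chaotic -> period-3 -> chaotic -> period-4."
    },
    "BL4": {
      "start": [2.42, 0.03],
      "end": [2.5, 0.004],
      "description": "Near-vertical cut at low I: period-1 -> chaotic -> period-2 -> period-3 -> period-4, with only the narrow chaotic region crossed (period-adding largely without chaos)."
    },
    "SL1": {
      "start": [2.36, 0.0265],
      "end": [3.63, 0.0095],
      "description": "Long oblique cut entering and leaving the comb-shaped region through a full doubling cascade on both sides: period-1 -> chaotic -> period-2 -> period-4 -> period-8 -> chaotic -> period-8 -> period-4 -> period-2 -> period-1."
    },
    "TL1": {
      "start": [2.98, 0.021],
      "end": [2.98, 0.0158],
      "description": "Short vertical cut through the edge of the period-4 island: period-2 -> period-4 -> period-8, a doubling sequence that stops short of chaos."
    },
    "TL2": {
      "start": [2.9, 0.019],
      "end": [2.9, 0.0125],
      "description": "Vertical cut showing the full doubling cascade into the comb-shaped region: period-2 -> period-4 -> period-8 -> chaotic."
    },
    "TL3": {
      "start": [2.9, 0.0125],
      "end": [2.9, 0.0055],
      "description": "Vertical cut through the period-adding-with-chaos zone: period-3 -> period-6 -> chaotic -> period-4 -> chaotic."
    },
    "TL4": {
      "start": [2.47, 0.01],
      "end": [2.5, 0.003],
      "description": "Low-I cut along the period-adding staircase without intervening chaos: period-2 -> period-3 -> period-4 -> period-5.  Useful for locating periodic-periodic boundaries (e.g. period-3/period-4) for noise-induced alternation studies."
    }
  }
}
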