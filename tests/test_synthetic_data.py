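"""Synthetic experiment-like records and their ground truth."""

import warnings

import numpy as np
import pytest

from hrchaos import HRParams
from hrchaos.errors import CannotGenerateError
from hrchaos.isi_analysis import EmbeddingConfig, npe_test
from hrchaos.parameter_space import LINE_PRESETS, ScanConfig
from hrchaos.regimes import classify_period, segment_scenario
from hrchaos.synthetic_data import (
    SyntheticSpec,
    gen_stationary,
    gen_stochastic_alternation,
    gen_washout,
    locate_period_boundary,
)

from conftest import CHAOTIC_POINT, PERIOD1_POINT, PERIOD2_POINT

# Operating point for noise-induced alternation: just inside the period-4
# side of the period-3/period-4 adding boundary on the low-I staircase
# (along the TL4 preset), with noise strong enough to kick the trajectory
# between the two patterns.
ALTERNATION_POINT = {"I": 2.492, "r": 0.0049}
ALTERNATION_NOISE = 0.05

# Tonic-spiking period-1/period-2 boundary: here the adjacent patterns
# differ by well under the measurement jitter, so the record carries no
# exploitable short-term structure (see the NPE test below).
TONIC_BOUNDARY = {"I": 3.5667, "r": 0.02}


def test_spec_validation():
    with pytest.raises(ValueError):
        SyntheticSpec(isi_jitter_cv=0.5)
    with pytest.raises(ValueError):
        SyntheticSpec(drift_profile="sudden")
    with pytest.raises(ValueError):
        SyntheticSpec(drift_line=LINE_PRESETS["BL1"])  # missing duration


def test_stationary_truth_matches_known_regimes():
    for point, kind, period in [
        (PERIOD1_POINT, "periodic", 1),
        (PERIOD2_POINT, "periodic", 2),
        (CHAOTIC_POINT, "chaotic", None),
    ]:
        spec = SyntheticSpec(base_params=HRParams(**point), seed=3)
        series, truth = gen_stationary(spec, n_isis=300)
        assert len(series) == 300
        assert (truth.kind, truth.period) == (kind, period)


def test_stationary_jittered_period_recoverable():
    spec = SyntheticSpec(base_params=HRParams(**PERIOD2_POINT), seed=5)
    series, truth = gen_stationary(spec, n_isis=300)
    # default 0.5% jitter stays within the noise-tolerant classifier band
    assert classify_period(series.isis[-150:], rel_tol=0.05) == truth.period


def test_stationary_deterministic_per_seed():
    spec = SyntheticSpec(base_params=HRParams(**PERIOD2_POINT), seed=9)
    a, _ = gen_stationary(spec, n_isis=100)
    b, _ = gen_stationary(spec, n_isis=100)
    c, _ = gen_stationary(SyntheticSpec(base_params=HRParams(**PERIOD2_POINT),
                                        seed=10), n_isis=100)
    np.testing.assert_array_equal(a.isis, b.isis)
    assert not np.array_equal(a.isis, c.isis)


def test_stationary_quantization_snaps_to_grid():
    rate = 10.0  # samples per model-time unit
    spec = SyntheticSpec(base_params=HRParams(**PERIOD1_POINT),
                         sampling_rate=rate, isi_jitter_cv=0.0, seed=0)
    series, _ = gen_stationary(spec, n_isis=100)
    frac = np.abs(series.isis * rate - np.round(series.isis * rate))
    assert np.max(frac) < 1e-9


def test_stationary_rejects_quiescent_point():
    spec = SyntheticSpec(base_params=HRParams(I=1.0, r=0.0245))
    with pytest.raises(CannotGenerateError):
        gen_stationary(spec, n_isis=100)


def test_locate_period_boundary_on_adding_staircase():
    a = (2.4835, 0.00685)   # period-3 side of the TL4 staircase
    b = (2.4955, 0.00405)   # period-4 side
    (I, r), k_a, k_b = locate_period_boundary(HRParams(), a, b, tol=1e-3)
    assert (k_a, k_b) == (3, 4)
    assert a[0] <= I <= b[0]
    assert b[1] <= r <= a[1]
    with pytest.raises(ValueError):
        locate_period_boundary(HRParams(), a, a, tol=1e-2)


def test_alternation_mixes_adjacent_periodic_patterns():
    p = HRParams(noise_intensity=ALTERNATION_NOISE, **ALTERNATION_POINT)
    series, truth = gen_stochastic_alternation(
        SyntheticSpec(base_params=p, seed=7), n_isis=500)
    assert truth.kind == "stochastic"
    # group the record into bursts (runs of short ISIs between long ones):
    # both the 3-spike and the 4-spike pattern must occur often
    v = series.isis
    sizes, cur = [], 0
    for x in v:
        if x > 60.0:
            sizes.append(cur)
            cur = 0
        else:
            cur += 1
    counts = np.bincount(np.asarray(sizes[1:]))
    assert counts[2] > 0.1 * len(sizes)
    assert counts[3] > 0.1 * len(sizes)


def test_alternation_with_tiny_noise_warns_periodic():
    p = HRParams(noise_intensity=1e-4, **ALTERNATION_POINT)
    with pytest.warns(UserWarning, match="noise too small"):
        _, truth = gen_stochastic_alternation(
            SyntheticSpec(base_params=p, seed=7), n_isis=300)
    assert truth.kind == "periodic"


# Washout drift routed along the long axis of the narrow chaotic band:
# entering and leaving chaos blends the slow-passage transition into the
# chaotic segment itself, so the stationary-truth order is recoverable.
# Periodic-to-periodic crossings are deliberately avoided: under slow
# drift a period-doubling is delayed past its static threshold (the
# splitting stays microscopic), and a period-adding crossing hesitates
# between the two patterns, so neither yields sharp boundaries.
WASHOUT_LINE = ("wash", (2.40, 0.0284), (2.62, 0.0189))
WASHOUT_DURATION = 200000.0
WASHOUT_WINDOW = 400


def _washout_line(n_points):
    from hrchaos.parameter_space import ParameterLine

    name, start, end = WASHOUT_LINE
    return ParameterLine(name, start, end, n_points)


def _washout_record(seed=2):
    spec = SyntheticSpec(drift_line=_washout_line(40), duration=WASHOUT_DURATION,
                         drift_profile="linear", seed=seed, isi_jitter_cv=0.002)
    return gen_washout(spec, prescan_points=40, scan=ScanConfig(rel_tol=0.05))


def test_washout_truth_segments_cover_record():
    record, truth = _washout_record()
    assert truth[0].start_index == 0
    assert truth[-1].end_index == len(record)
    for a, b in zip(truth, truth[1:]):
        assert a.end_index == b.start_index
    labels = [str(s.label) for s in truth]
    assert labels == ["period-1", "chaotic", "period-2"]


def test_washout_segmentation_recovers_truth_within_one_window():
    record, truth = _washout_record()
    segs = segment_scenario(record, window=WASHOUT_WINDOW)
    assert [str(s.label) for s in segs] == [str(s.label) for s in truth]
    for got, want in zip(segs, truth):
        assert abs(got.start_index - want.start_index) <= WASHOUT_WINDOW
        assert abs(got.end_index - want.end_index) <= WASHOUT_WINDOW


def test_washout_reversed_drift_reverses_sequence():
    from hrchaos.parameter_space import ParameterLine

    name, start, end = WASHOUT_LINE
    rev = ParameterLine(name, end, start, 40)
    spec = SyntheticSpec(drift_line=rev, duration=WASHOUT_DURATION,
                         drift_profile="linear", seed=2, isi_jitter_cv=0.002)
    _, truth = gen_washout(spec, prescan_points=40, scan=ScanConfig(rel_tol=0.05))
    assert [str(s.label) for s in truth] == ["period-2", "chaotic", "period-1"]


def test_washout_deterministic_per_seed():
    spec = SyntheticSpec(drift_line=_washout_line(10), duration=8000.0, seed=4)
    a, _ = gen_washout(spec, prescan_points=10)
    b, _ = gen_washout(spec, prescan_points=10)
    np.testing.assert_array_equal(a.isis, b.isis)


def test_alternation_record_not_deterministic_chaotic_record_is():
    p = HRParams(noise_intensity=0.01, **TONIC_BOUNDARY)
    alt, _ = gen_stochastic_alternation(
        SyntheticSpec(base_params=p, seed=13, isi_jitter_cv=0.1), n_isis=500)
    cha, _ = gen_stationary(
        SyntheticSpec(base_params=HRParams(**CHAOTIC_POINT), seed=13),
        n_isis=500)
    res_alt = npe_test(alt, EmbeddingConfig(seed=0))
    res_cha = npe_test(cha, EmbeddingConfig(seed=0))
    assert not res_alt.deterministic_at(1)
    assert res_cha.deterministic_at(1)
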