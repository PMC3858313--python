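"""Experiment-like ISI records with known ground truth.

Real recordings from a spontaneously firing injured-nerve site reduce, in
this pipeline, to an ISI series digitized at a finite sampling rate and
carrying proportional measurement/physiological jitter; slow washout of
extracellular calcium makes the effective model parameters drift, so a
single record traverses an ordered sequence of firing regimes.  The
generators here emulate exactly those three features on top of the model:

* :func:`gen_stationary` - fixed parameters, optional spike-time
  quantization and multiplicative ISI jitter;
* :func:`gen_stochastic_alternation` - additive channel-like noise at a
  period-adding boundary, producing irregular alternation between the
  adjacent period-k and period-(k+1) patterns ("stochastic firing");
* :func:`gen_washout` - parameters drifting along a line in the (I, r)
  plane, with the true regime schedule from a stationary pre-scan.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import _kernels
from .errors import CannotGenerateError, IntegrationBlowUpError
from .hr_model import (
    DEFAULT_DT,
    DEFAULT_INITIAL,
    DEFAULT_MIN_SEPARATION,
    DEFAULT_SPIKE_THRESHOLD,
    DEFAULT_TRANSIENT,
    HRParams,
    ISISeries,
    simulate_isis,
)
from .parameter_space import ParameterLine, ScanConfig, extract_scenario, scan_line
from .regimes import APERIODIC, RegimeLabel, RegimeSegment, classify_period, classify_point

__all__ = [
    "SyntheticSpec",
    "gen_stationary",
    "gen_stochastic_alternation",
    "gen_washout",
    "locate_period_boundary",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic record.

    ``isi_jitter_cv`` is the coefficient of variation of multiplicative
    Gaussian jitter applied to each ISI (proportional measurement and
    physiological variability; default 0.5%).  ``sampling_rate`` (samples
    per model-time unit), when set, quantizes spike times to the digitizer
    grid before ISIs are formed.  ``drift_line``/``drift_profile``/
    ``duration`` describe slow parameter drift for washout records.
    """

    base_params: HRParams = field(default_factory=HRParams)
    drift_line: Optional[ParameterLine] = None
    drift_profile: str = "exponential"  # or "linear"
    duration: Optional[float] = None    # model time of the drift
    isi_jitter_cv: float = 0.005
    sampling_rate: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.isi_jitter_cv < 0.2:
            raise ValueError("isi_jitter_cv must lie in [0, 0.2)")
        if self.drift_profile not in ("linear", "exponential"):
            raise ValueError("drift_profile must be 'linear' or 'exponential'")
        if self.drift_line is not None and not (self.duration and self.duration > 0):
            raise ValueError("duration must be positive when drift_line is present")


def _quantize(times: np.ndarray, rate: Optional[float]) -> np.ndarray:
    if rate is None:
        return times
    return np.round(times * rate) / rate


def _jitter_isis(isis: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    if cv == 0:
        return isis
    factors = 1.0 + cv * rng.standard_normal(len(isis))
    return isis * np.clip(factors, 0.05, None)


def gen_stationary(spec: SyntheticSpec, n_isis: int = 500):
    """Stationary record at fixed parameters, with its true regime label.

    The noiseless model is integrated until ``n_isis`` post-transient
    ISIs are collected; spike times are quantized (if a sampling rate is
    set) and ISIs jittered multiplicatively.  The ground-truth label is
    the noiseless classification of the same parameter point.

    Returns (ISISeries, RegimeLabel).
    """
    if spec.drift_line is not None:
        raise ValueError("gen_stationary requires a spec without drift")
    params = replace(spec.base_params, noise_intensity=0.0)
    try:
        isis = simulate_isis(params, n_isis=n_isis, t_end=4000.0)
    except IntegrationBlowUpError as exc:
        raise CannotGenerateError(f"model blew up at t={exc.time:g}") from exc
    if len(isis) < n_isis:
        raise CannotGenerateError(
            f"parameters yield too few spikes ({len(isis)} ISIs); "
            "quiescent or near-quiescent point")
    rng = np.random.default_rng(spec.seed)
    times = np.concatenate([[0.0], np.cumsum(isis.isis)])
    qisis = np.diff(_quantize(times, spec.sampling_rate))
    values = _jitter_isis(qisis, spec.isi_jitter_cv, rng)
    truth = classify_point(params)
    return ISISeries(values, units=isis.units), truth


def locate_period_boundary(
    base_params: HRParams,
    point_a: tuple,
    point_b: tuple,
    *,
    tol: float = 1e-4,
    scan: Optional[ScanConfig] = None,
) -> tuple:
    """Bisect the segment point_a -> point_b for a period-label change.

    Both endpoints must classify as periodic with different periods under
    the noiseless model; returns the (I, r) point of the boundary (to a
    relative segment tolerance ``tol``) together with the two periods:
    ((I, r), k_a, k_b).
    """
    cfg = scan if scan is not None else ScanConfig()

    def period_at(t: float):
        I = point_a[0] + t * (point_b[0] - point_a[0])
        r = point_a[1] + t * (point_b[1] - point_a[1])
        params = base_params.with_point(I=I, r=r)
        isis = simulate_isis(params, n_isis=cfg.n_isis, t_end=cfg.t_end,
                             dt=cfg.dt, transient=cfg.transient)
        if len(isis) < 4 * cfg.k_max:
            return None
        return classify_period(isis, rel_tol=cfg.rel_tol, k_max=cfg.k_max,
                               tail=max(4 * cfg.k_max, len(isis) // 2))

    k_a, k_b = period_at(0.0), period_at(1.0)
    if k_a in (None, APERIODIC) or k_b in (None, APERIODIC) or k_a == k_b:
        raise ValueError(
            f"endpoints must be periodic with different periods, got {k_a!r}, {k_b!r}")
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        k_mid = period_at(mid)
        if k_mid == k_a:
            lo = mid
        else:
            hi = mid
    t_star = 0.5 * (lo + hi)
    I = point_a[0] + t_star * (point_b[0] - point_a[0])
    r = point_a[1] + t_star * (point_b[1] - point_a[1])
    return (I, r), k_a, k_b


def gen_stochastic_alternation(spec: SyntheticSpec, n_isis: int = 500):
    """Noise-induced alternation at a period-adding boundary.

    ``spec.base_params`` must sit at (or very near) a period-adding
    bifurcation point - use :func:`locate_period_boundary` - and carry
    ``noise_intensity > 0``.  Channel-like additive noise then makes the
    firing alternate irregularly between the adjacent period-k and
    period-(k+1) patterns.  If the noise is too small to induce
    alternation within the run, a warning is issued and the true label is
    periodic instead of stochastic.

    Returns (ISISeries, RegimeLabel).
    """
    if spec.drift_line is not None:
        raise ValueError("gen_stochastic_alternation requires a spec without drift")
    params = spec.base_params
    rng = np.random.default_rng(spec.seed)
    em_seed = int(rng.integers(0, 2 ** 31 - 1))
    if params.noise_intensity > 0:
        sim_params = replace(params)
    else:
        sim_params = params  # degenerate noiseless control
    try:
        isis = simulate_isis(sim_params, n_isis=n_isis, t_end=4000.0, seed=em_seed)
    except IntegrationBlowUpError as exc:
        raise CannotGenerateError(f"model blew up at t={exc.time:g}") from exc
    if len(isis) < n_isis:
        raise CannotGenerateError("too few spikes at the requested parameters")
    times = np.concatenate([[0.0], np.cumsum(isis.isis)])
    qisis = np.diff(_quantize(times, spec.sampling_rate))
    values = _jitter_isis(qisis, spec.isi_jitter_cv, rng)
    k = classify_period(values, rel_tol=0.05, k_max=8) if len(values) >= 32 else APERIODIC
    if params.noise_intensity == 0 or k != APERIODIC:
        if params.noise_intensity > 0:
            warnings.warn("noise too small to induce alternation; record is periodic")
        truth = RegimeLabel("periodic", period=int(k) if k != APERIODIC else 1,
                            evidence={"noise_intensity": params.noise_intensity})
    else:
        truth = RegimeLabel("stochastic",
                            evidence={"noise_intensity": params.noise_intensity})
    return ISISeries(values, units=isis.units), truth


def gen_washout(spec: SyntheticSpec, *, prescan_points: int = 60,
                scan: Optional[ScanConfig] = None):
    """Nonstationary record with (I, r) drifting along ``spec.drift_line``.

    Parameters are updated continuously at every integration step while
    moving from the line's start to its end over ``spec.duration`` model-
    time units, following the linear or exponential-approach profile (the
    latter mirrors a washout, fast at first and leveling off; time
    constant duration/3, rescaled to land exactly on the end point).

    The ground-truth regime schedule comes from a stationary pre-scan of
    the same line: its scenario boundaries (fractions along the line) are
    mapped through the drift profile to record times and then to ISI
    indices.

    Returns (ISISeries with origin_times, list[RegimeSegment]).
    """
    if spec.drift_line is None:
        raise ValueError("gen_washout requires a drift_line")
    line = spec.drift_line
    duration = float(spec.duration)
    params = spec.base_params
    p0 = params.to_vector()
    (I0, r0), (I1, r1) = tuple(line.start), tuple(line.end)
    rng = np.random.default_rng(spec.seed)
    em_seed = int(rng.integers(0, 2 ** 31 - 1))
    exponential = spec.drift_profile == "exponential"
    tau = duration / 3.0
    state0 = np.asarray(DEFAULT_INITIAL, dtype=float)
    max_spikes = int(duration / DEFAULT_MIN_SEPARATION) + 16
    times, final, blow = _kernels.drift_spike_times(
        state0, duration, DEFAULT_DT, p0, I0, I1, r0, r1,
        exponential, tau, params.noise_intensity, em_seed,
        DEFAULT_SPIKE_THRESHOLD, DEFAULT_MIN_SEPARATION, 0.0, max_spikes)
    truncated = blow >= 0
    if truncated:
        warnings.warn(f"integration blew up at t={blow:g}; record truncated")
    if len(times) < 2:
        raise CannotGenerateError("drift produced fewer than 2 spikes")
    qtimes = _quantize(times, spec.sampling_rate)
    isis = np.diff(qtimes)
    isis = _jitter_isis(isis, spec.isi_jitter_cv, rng)
    record = ISISeries(isis, origin_times=qtimes[1:].copy())

    # ground truth: stationary pre-scan of the same line
    if tuple(line.start) == tuple(line.end):
        truth_label = classify_point(replace(params, noise_intensity=0.0)
                                     .with_point(I=I0, r=r0))
        return record, [RegimeSegment(label=truth_label, start_index=0,
                                      end_index=len(isis),
                                      start_time=float(qtimes[1]),
                                      end_time=float(qtimes[-1]))]
    cfg = scan if scan is not None else ScanConfig(
        base_params=replace(params, noise_intensity=0.0))
    diagram = scan_line(line.with_points(prescan_points), cfg)
    steps = extract_scenario(diagram)

    def frac_to_time(f: float) -> float:
        if not exponential:
            return f * duration
        end_scale = 1.0 - np.exp(-duration / tau)
        f = min(f * end_scale, 1.0 - 1e-12)
        return -tau * np.log(1.0 - f)

    segments = []
    spike_t = qtimes[1:]
    prev_idx = 0
    for step in steps:
        f_end = (step.end_index) / prescan_points
        t_end_seg = frac_to_time(min(f_end, 1.0))
        idx = int(np.searchsorted(spike_t, t_end_seg)) if step is not steps[-1] else len(isis)
        idx = min(max(idx, prev_idx + 1), len(isis))
        segments.append(RegimeSegment(
            label=step.label, start_index=prev_idx, end_index=idx,
            start_time=float(spike_t[prev_idx]), end_time=float(spike_t[idx - 1])))
        prev_idx = idx
        if prev_idx >= len(isis):
            break
    return record, segments
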