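"""Firing-regime classification of ISI series and model parameter points.

A firing pattern is *period-k* when its ISI sequence repeats every k
intervals (k distinct ISIs per cycle).  Aperiodic model points are called
*chaotic* when the largest Lyapunov exponent is positive; aperiodic data
series are called *chaotic* when they show nonlinear short-term
predictability beyond random-shuffle surrogates, and *stochastic*
otherwise.  Nonstationary records are segmented into ordered sequences of
such labels by a sliding window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InsufficientDataError
from .hr_model import (
    DEFAULT_DT,
    DEFAULT_INITIAL,
    DEFAULT_TRANSIENT,
    HRParams,
    ISISeries,
    State,
    largest_lyapunov,
    simulate_isis,
)

__all__ = [
    "RegimeLabel",
    "RegimeSegment",
    "APERIODIC",
    "classify_period",
    "classify_point",
    "classify_series",
    "segment_scenario",
]

#: Sentinel returned by :func:`classify_period` when no period fits.
APERIODIC = "aperiodic"

DEFAULT_REL_TOL = 0.01          # noiseless model series
DEFAULT_REL_TOL_NOISY = 0.05    # jittered / experimental-like series
DEFAULT_K_MAX = 8
DEFAULT_LLE_THRESHOLD = 0.001   # per model-time unit


@dataclass(frozen=True)
class RegimeLabel:
    """Classification outcome with the diagnostics that produced it."""

    kind: str  # periodic | chaotic | stochastic | quiescent | unclassified
    period: Optional[int] = None
    evidence: dict = field(default_factory=dict)

    _KINDS = ("periodic", "chaotic", "stochastic", "quiescent", "unclassified")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown regime kind {self.kind!r}")
        if (self.kind == "periodic") != (self.period is not None):
            raise ValueError("period must be present iff kind == 'periodic'")
        if self.period is not None and self.period < 1:
            raise ValueError("period must be >= 1")

    def same_regime(self, other: "RegimeLabel") -> bool:
        return self.kind == other.kind and self.period == other.period

    def __str__(self) -> str:
        return f"period-{self.period}" if self.kind == "periodic" else self.kind

    def to_dict(self) -> dict:
        return {"kind": self.kind, "period": self.period,
                "evidence": {k: (None if v is None else float(v) if isinstance(v, (int, float, np.floating)) else v)
                             for k, v in self.evidence.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "RegimeLabel":
        return cls(kind=d["kind"], period=d.get("period"),
                   evidence=dict(d.get("evidence", {})))


@dataclass
class RegimeSegment:
    """A half-open stretch [start_index, end_index) of one regime."""

    label: RegimeLabel
    start_index: int
    end_index: int
    start_time: Optional[float] = None
    end_time: Optional[float] = None

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ValueError("end_index must exceed start_index")

    def __len__(self) -> int:
        return self.end_index - self.start_index

    def to_dict(self) -> dict:
        d = self.label.to_dict()
        d.update(start_index=int(self.start_index), end_index=int(self.end_index),
                 start_time=self.start_time, end_time=self.end_time)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RegimeSegment":
        return cls(label=RegimeLabel.from_dict(d),
                   start_index=d["start_index"], end_index=d["end_index"],
                   start_time=d.get("start_time"), end_time=d.get("end_time"))


def _as_values(isis) -> np.ndarray:
    if isinstance(isis, ISISeries):
        return isis.isis
    return np.asarray(isis, dtype=float)


def classify_period(
    isis,
    rel_tol: float = DEFAULT_REL_TOL,
    k_max: int = DEFAULT_K_MAX,
    tail: Optional[int] = None,
):
    """Smallest period k <= k_max fitting the series, or ``APERIODIC``.

    The series (or its last ``tail`` values) is period-k when every lag-k
    difference is below ``rel_tol`` times the mean ISI.  The smallest
    admissible k wins, so an exact period-2 series is never reported as
    period-4.
    """
    v = _as_values(isis)
    if tail is not None:
        v = v[-tail:]
    if len(v) < 4 * k_max:
        raise InsufficientDataError(
            f"period classification needs >= {4 * k_max} ISIs, got {len(v)}")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("mean ISI must be positive")
    for k in range(1, k_max + 1):
        if np.max(np.abs(v[k:] - v[:-k])) / mean < rel_tol:
            return k
    return APERIODIC


def classify_point(
    params: HRParams,
    *,
    n_isis: int = 120,
    rel_tol: float = DEFAULT_REL_TOL,
    k_max: int = DEFAULT_K_MAX,
    lle_threshold: float = DEFAULT_LLE_THRESHOLD,
    dt: float = DEFAULT_DT,
    transient: float = DEFAULT_TRANSIENT,
    t_end: float = 6000.0,
    lle_t_average: float = 5000.0,
    initial: State | tuple = DEFAULT_INITIAL,
    return_final_state: bool = False,
):
    """Classify a noiseless parameter point by simulation.

    Quiescent when fewer than two post-transient spikes appear;
    periodic(k) per :func:`classify_period` on the ISI tail; otherwise
    chaotic iff the largest Lyapunov exponent exceeds ``lle_threshold``
    (aperiodic points below it stay unclassified, guarding against long
    transients masquerading as chaos).
    """
    if params.noise_intensity > 0:
        raise ValueError("classify_point requires the noiseless model")
    isis, final = simulate_isis(
        params, n_isis=n_isis, t_end=t_end, dt=dt, transient=transient,
        initial=initial, return_final_state=True)
    evidence: dict = {"n_isis": len(isis)}
    if len(isis) < 1:
        label = RegimeLabel("quiescent", evidence=evidence)
        return (label, final) if return_final_state else label
    if len(isis) < 4 * k_max:
        label = RegimeLabel("unclassified", evidence=evidence)
        return (label, final) if return_final_state else label
    evidence["period_tol_used"] = rel_tol
    k = classify_period(isis, rel_tol=rel_tol, k_max=k_max,
                        tail=max(4 * k_max, len(isis) // 2))
    if k != APERIODIC:
        label = RegimeLabel("periodic", period=k, evidence=evidence)
        return (label, final) if return_final_state else label
    lle = largest_lyapunov(params, t_transient=0.0, t_average=lle_t_average,
                           dt=dt, initial=final.to_array())
    evidence["lle"] = lle
    kind = "chaotic" if lle > lle_threshold else "unclassified"
    label = RegimeLabel(kind, evidence=evidence)
    return (label, final) if return_final_state else label


def classify_series(
    isis,
    *,
    rel_tol: float = DEFAULT_REL_TOL_NOISY,
    k_max: int = DEFAULT_K_MAX,
    min_len: int = 200,
    embedding=None,
) -> RegimeLabel:
    """Classify a recorded ISI series: periodic, chaotic or stochastic.

    Data-only counterpart of :func:`classify_point` for records where no
    Lyapunov exponent is available.  Aperiodic series are tested for
    determinism with the normalized prediction error at step 1: chaotic
    when it falls below the shuffle-surrogate ensemble mean minus three
    standard deviations, stochastic otherwise.
    """
    from .isi_analysis import EmbeddingConfig, npe_test

    v = _as_values(isis)
    if len(v) < min_len:
        raise InsufficientDataError(
            f"series classification needs >= {min_len} ISIs, got {len(v)}")
    evidence: dict = {"period_tol_used": rel_tol}
    k = classify_period(v, rel_tol=rel_tol, k_max=k_max)
    if k != APERIODIC:
        return RegimeLabel("periodic", period=k, evidence=evidence)
    cfg = embedding if embedding is not None else EmbeddingConfig()
    res = npe_test(v, cfg)
    h1 = 0
    evidence.update(
        npe_h1=float(res.npe_original[h1]),
        surr_mean_h1=float(res.npe_surrogate_mean[h1]),
        surr_sd_h1=float(res.npe_surrogate_sd[h1]),
    )
    cut = res.npe_surrogate_mean[h1] - 3.0 * res.npe_surrogate_sd[h1]
    kind = "chaotic" if res.npe_original[h1] < cut else "stochastic"
    return RegimeLabel(kind, evidence=evidence)


def segment_scenario(
    isis,
    window: int = 100,
    *,
    rel_tol: float = DEFAULT_REL_TOL_NOISY,
    k_max: int = DEFAULT_K_MAX,
    min_npe_len: int = 100,
    embedding=None,
) -> list[RegimeSegment]:
    """Segment a nonstationary ISI record into an ordered regime sequence.

    A window of ``window`` ISIs slides one step at a time; each window is
    classified by period (noise-tolerant tolerance).  Runs of equal labels
    become segments with boundaries at the transition window's centre;
    segments shorter than ``window`` are absorbed into the longer
    neighbour.  Aperiodic segments long enough for the surrogate test are
    then resolved into chaotic vs stochastic, shorter ones stay
    unclassified.
    """
    series = isis if isinstance(isis, ISISeries) else ISISeries(np.asarray(isis, float))
    v = series.isis
    n = len(v)
    if n < 2 * window:
        raise InsufficientDataError(
            f"segmentation needs >= {2 * window} ISIs, got {n}")
    if window < 4 * k_max:
        raise ValueError("window must hold at least 4*k_max ISIs")

    # pass 1: per-window period label (int k, or -1 for aperiodic)
    n_win = n - window + 1
    win_labels = np.empty(n_win, dtype=int)
    for i in range(n_win):
        k = classify_period(v[i:i + window], rel_tol=rel_tol, k_max=k_max)
        win_labels[i] = -1 if k == APERIODIC else k

    # pass 2: run-length encode window labels -> candidate boundaries at
    # transition-window centres, then drop runs shorter than `window`
    runs: list[list[int]] = []  # [label, start_window, end_window)
    start = 0
    for i in range(1, n_win):
        if win_labels[i] != win_labels[start]:
            runs.append([win_labels[start], start, i])
            start = i
    runs.append([win_labels[start], start, n_win])
    while len(runs) > 1:
        lengths = [rn[2] - rn[1] for rn in runs]
        j = int(np.argmin(lengths))
        if lengths[j] >= window:
            break
        # absorb shortest run into its longer neighbour
        if j == 0:
            runs[1][1] = runs[0][1]
            runs.pop(0)
        elif j == len(runs) - 1:
            runs[-2][2] = runs[-1][2]
            runs.pop()
        else:
            left_len = runs[j - 1][2] - runs[j - 1][1]
            right_len = runs[j + 1][2] - runs[j + 1][1]
            if left_len >= right_len:
                runs[j - 1][2] = runs[j][2]
            else:
                runs[j + 1][1] = runs[j][1]
            runs.pop(j)
        # merge adjacent runs that became equal-labelled
        merged = [runs[0]]
        for rn in runs[1:]:
            if rn[0] == merged[-1][0]:
                merged[-1][2] = rn[2]
            else:
                merged.append(rn)
        runs = merged

    half = window // 2
    segments: list[RegimeSegment] = []
    for idx, (lab, w_start, w_end) in enumerate(runs):
        i0 = 0 if idx == 0 else w_start + half
        i1 = n if idx == len(runs) - 1 else runs[idx + 1][1] + half
        seg_v = v[i0:i1]
        if lab >= 1:
            label = RegimeLabel("periodic", period=int(lab),
                                evidence={"period_tol_used": rel_tol})
        else:
            label = _resolve_aperiodic(seg_v, min_npe_len, embedding)
        times = series.origin_times
        segments.append(RegimeSegment(
            label=label, start_index=i0, end_index=i1,
            start_time=None if times is None else float(times[i0]),
            end_time=None if times is None else float(times[i1 - 1]),
        ))
    return segments


def _resolve_aperiodic(values: np.ndarray, min_npe_len: int, embedding) -> RegimeLabel:
    """Chaotic vs stochastic for an aperiodic stretch, by the NPE test."""
    from .isi_analysis import EmbeddingConfig, npe_test

    if len(values) < min_npe_len:
        return RegimeLabel("unclassified", evidence={"n_isis": len(values)})
    cfg = embedding if embedding is not None else EmbeddingConfig()
    res = npe_test(values, cfg)
    cut = res.npe_surrogate_mean[0] - 3.0 * res.npe_surrogate_sd[0]
    kind = "chaotic" if res.npe_original[0] < cut else "stochastic"
    return RegimeLabel(kind, evidence={
        "npe_h1": float(res.npe_original[0]),
        "surr_mean_h1": float(res.npe_surrogate_mean[0]),
        "surr_sd_h1": float(res.npe_surrogate_sd[0]),
    })
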