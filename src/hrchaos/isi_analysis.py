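"""Determinism diagnostics for interspike-interval series.

The core statistic is the normalized prediction error (NPE) of a simple
nearest-neighbor forecaster in a delay-embedded state space: the series is
embedded as points X_i = (s_i, ..., s_{i+m-1}); the h-step future of X_i
is predicted as the mean future of its k nearest neighbors, and the RMS
prediction error is normalized by the RMS error of predicting the series
mean.  NPE well below 1 means short-term predictability beyond the
mean-value baseline; random-shuffle surrogates (which preserve the value
distribution but destroy temporal order) supply the null ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist

from .errors import DegenerateSeriesError, InsufficientDataError
from .hr_model import ISISeries

__all__ = [
    "ReturnMap",
    "EmbeddingConfig",
    "NPEResult",
    "first_return_map",
    "delay_embed",
    "npe",
    "surrogate_shuffle",
    "npe_test",
]


@dataclass
class ReturnMap:
    """Ordered (ISI_i, ISI_{i+1}) pairs of a series."""

    pairs: np.ndarray  # shape (n-1, 2)

    def __len__(self) -> int:
        return len(self.pairs)

    def distinct_points(self, decimals: int = 3) -> int:
        """Number of distinct pairs after rounding (structure diagnostic)."""
        return len(np.unique(np.round(self.pairs, decimals), axis=0))


@dataclass(frozen=True)
class EmbeddingConfig:
    """Settings for the nearest-neighbor prediction test.

    ``eps`` is the neighbor fraction: k = max(1, round(eps * P)) of the P
    valid embedded points are used as neighbors (self excluded, plus a
    Theiler exclusion of ``theiler`` indices on each side when set).
    """

    m: int = 4
    eps: float = 0.01
    h_max: int = 10
    n_surrogates: int = 10
    seed: int = 0
    theiler: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.eps < 1:
            raise ValueError("eps must lie in (0, 1)")
        if self.m < 1 or self.h_max < 1 or self.n_surrogates < 1:
            raise ValueError("m, h_max and n_surrogates must be >= 1")


@dataclass
class NPEResult:
    """NPE vs prediction step for a series and its surrogate ensemble."""

    h_values: np.ndarray
    npe_original: np.ndarray
    npe_surrogate_mean: np.ndarray
    npe_surrogate_sd: np.ndarray
    npe_surrogates: np.ndarray  # shape (n_surrogates, h_max)
    config: EmbeddingConfig

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "h": self.h_values,
            "npe": self.npe_original,
            "surr_mean": self.npe_surrogate_mean,
            "surr_sd": self.npe_surrogate_sd,
        })

    def deterministic_at(self, h: int = 1, n_sd: float = 3.0) -> bool:
        """Original below surrogate mean - n_sd * sd at step h."""
        i = int(np.searchsorted(self.h_values, h))
        return bool(self.npe_original[i]
                    < self.npe_surrogate_mean[i] - n_sd * self.npe_surrogate_sd[i])


def _values(series) -> np.ndarray:
    if isinstance(series, ISISeries):
        return series.isis
    return np.asarray(series, dtype=float)


def first_return_map(isis) -> ReturnMap:
    """First return map: pairs (ISI_i, ISI_{i+1}) in series order."""
    v = _values(isis)
    if len(v) < 2:
        raise InsufficientDataError("return map needs at least 2 ISIs")
    return ReturnMap(pairs=np.column_stack([v[:-1], v[1:]]))


def delay_embed(series, m: int) -> np.ndarray:
    """Delay embedding with unit delay: rows X_i = (s_i, ..., s_{i+m-1})."""
    v = _values(series)
    if m < 1:
        raise ValueError("m must be >= 1")
    if len(v) < m:
        raise InsufficientDataError(f"series of length {len(v)} cannot embed with m={m}")
    return sliding_window_view(v, m).copy()


def _npe_one(v: np.ndarray, embed: np.ndarray, m: int, eps: float, h: int,
             theiler: int) -> float:
    """NPE at a single prediction step (brute-force all-pairs neighbors)."""
    n = len(v)
    n_valid = n - (m - 1) - h  # base points with an h-step future
    X = embed[:n_valid]
    futures = v[m - 1 + h:]
    assert len(futures) == n_valid
    k = max(1, int(round(eps * n_valid)))
    D = cdist(X, X)
    idx = np.arange(n_valid)
    for off in range(-theiler, theiler + 1):
        j = idx + off
        ok = (j >= 0) & (j < n_valid)
        D[idx[ok], j[ok]] = np.inf
    # stable sort: distance ties resolved toward the smaller column index
    order = np.argsort(D, axis=1, kind="stable")
    neigh = order[:, :k]
    pred = futures[neigh].mean(axis=1)
    err = pred - futures
    xbar = v.mean()
    denom = np.sqrt(np.mean((futures - xbar) ** 2))
    if denom == 0:
        raise DegenerateSeriesError("constant futures: NPE undefined")
    return float(np.sqrt(np.mean(err ** 2)) / denom)


def npe(series, m: int = 4, eps: float = 0.01, h: int = 1,
        theiler: int = 0) -> float:
    """Normalized prediction error at step ``h``.

    For each embedded point with an h-step future, the future value
    s_{i+m-1+h} is predicted as the mean future of the k = max(1,
    round(eps*P)) nearest other points (Euclidean distance, ties broken
    toward the smaller index).  The RMS of these errors is divided by the
    RMS error of the whole-series mean as predictor.
    """
    v = _values(series)
    if len(v) < m + h + 10:
        raise InsufficientDataError(
            f"NPE needs at least m+h+10 = {m + h + 10} values, got {len(v)}")
    if np.var(v) == 0:
        raise DegenerateSeriesError("series has zero variance")
    embed = sliding_window_view(v, m)
    return _npe_one(v, embed, m, eps, h, theiler)


def surrogate_shuffle(series, seed: int) -> np.ndarray:
    """Random permutation of the series (the value multiset is preserved)."""
    v = _values(series)
    if len(v) < 2:
        raise InsufficientDataError("surrogate needs at least 2 values")
    rng = np.random.default_rng(seed)
    return rng.permutation(v)


def npe_test(series, config: Optional[EmbeddingConfig] = None) -> NPEResult:
    """NPE over h = 1..h_max for the original series and shuffled surrogates.

    Surrogate seeds are drawn from a generator seeded with
    ``config.seed``, so the whole result is reproducible bit for bit.
    """
    cfg = config if config is not None else EmbeddingConfig()
    v = _values(series)
    if len(v) < cfg.m + cfg.h_max + 10:
        raise InsufficientDataError(
            f"NPE test needs at least {cfg.m + cfg.h_max + 10} values, got {len(v)}")
    if np.var(v) == 0:
        raise DegenerateSeriesError("series has zero variance")

    h_values = np.arange(1, cfg.h_max + 1)

    def curve(series_values: np.ndarray) -> np.ndarray:
        embed = sliding_window_view(series_values, cfg.m)
        return np.array([
            _npe_one(series_values, embed, cfg.m, cfg.eps, int(h), cfg.theiler)
            for h in h_values
        ])

    npe_orig = curve(v)
    rng = np.random.default_rng(cfg.seed)
    surr_seeds = rng.integers(0, 2 ** 31 - 1, size=cfg.n_surrogates)
    npe_surr = np.array([curve(surrogate_shuffle(v, int(s))) for s in surr_seeds])
    return NPEResult(
        h_values=h_values,
        npe_original=npe_orig,
        npe_surrogate_mean=npe_surr.mean(axis=0),
        npe_surrogate_sd=npe_surr.std(axis=0, ddof=1),
        npe_surrogates=npe_surr,
        config=cfg,
    )
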