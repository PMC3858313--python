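"""Hindmarsh-Rose neuron model: integration, spikes, ISIs, Lyapunov exponent.

The model is the classic three-variable slow-fast burster

    dx/dt = y - a*x^3 + b*x^2 - z + I
    dy/dt = c - d*x^2 - y
    dz/dt = r*(s*(x - x_rest) - z)

with x the membrane potential, y the fast recovery variable and z the slow
adaption current.  The two bifurcation parameters studied here are the
injected current I and the slow time-scale constant r; the remaining six
constants are held at their standard values a=1, b=3, c=1, d=5, s=4,
x_rest=-1.6.  All quantities are dimensionless and times are in model-time
units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import _kernels
from .errors import InsufficientSpikesError, IntegrationBlowUpError

__all__ = [
    "HRParams",
    "State",
    "Trajectory",
    "SpikeTrain",
    "ISISeries",
    "DEFAULT_DT",
    "DEFAULT_TRANSIENT",
    "DEFAULT_SPIKE_THRESHOLD",
    "DEFAULT_MIN_SEPARATION",
    "hr_derivative",
    "jacobian",
    "integrate",
    "detect_spikes",
    "isis_from_spikes",
    "simulate_isis",
    "largest_lyapunov",
]

DEFAULT_DT = 0.01
DEFAULT_TRANSIENT = 500.0
DEFAULT_SPIKE_THRESHOLD = 0.0
DEFAULT_MIN_SEPARATION = 1.0

#: Initial condition used throughout when none is given.  Any point in the
#: basin of the firing attractor works; this one sits near the attractor
#: for the parameter ranges studied here.
DEFAULT_INITIAL = (-1.0, 0.0, 2.0)


@dataclass(frozen=True)
class HRParams:
    """Model constants plus the two bifurcation parameters and noise level.

    ``noise_intensity`` is the standard deviation scale of additive white
    noise; it enters the y-equation (or the x-equation when
    ``noise_on_x``) under Euler-Maruyama integration.
    """

    a: float = 1.0
    b: float = 3.0
    c: float = 1.0
    d: float = 5.0
    s: float = 4.0
    x_rest: float = -1.6
    r: float = 0.0245
    I: float = 2.53
    noise_intensity: float = 0.0
    noise_on_x: bool = False

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"r must be positive, got {self.r}")
        if self.noise_intensity < 0:
            raise ValueError("noise_intensity must be >= 0")

    def to_vector(self) -> np.ndarray:
        """Flat parameter vector in the order the compiled kernels expect."""
        return np.array(
            [self.a, self.b, self.c, self.d, self.s, self.x_rest, self.r, self.I]
        )

    def with_point(self, I: float, r: float) -> "HRParams":
        return replace(self, I=I, r=r)


@dataclass(frozen=True)
class State:
    x: float
    y: float
    z: float

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @classmethod
    def from_array(cls, arr) -> "State":
        return cls(float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class Trajectory:
    """Equally spaced state history (times[i] = i*dt from the start time)."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 3), columns x, y, z
    params: HRParams

    @property
    def x(self) -> np.ndarray:
        return self.states[:, 0]

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.times, "x": self.states[:, 0],
             "y": self.states[:, 1], "z": self.states[:, 2]}
        )


@dataclass
class SpikeTrain:
    """Times of spike maxima, strictly increasing."""

    spike_times: np.ndarray
    units: str = "model_time"

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if len(self.spike_times) > 1 and not np.all(np.diff(self.spike_times) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.spike_times)


@dataclass
class ISISeries:
    """Ordered interspike intervals with a units tag."""

    isis: np.ndarray
    units: str = "model_time"
    origin_times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.isis = np.asarray(self.isis, dtype=float)
        if len(self.isis) and not np.all(self.isis > 0):
            raise ValueError("all ISIs must be positive")

    def __len__(self) -> int:
        return len(self.isis)

    def values(self) -> np.ndarray:
        return self.isis


def hr_derivative(state: State, params: HRParams) -> State:
    """Right-hand side of the model equations at ``state``."""
    dx, dy, dz = _kernels.deriv(state.x, state.y, state.z, params.to_vector())
    return State(dx, dy, dz)


def jacobian(state: State, params: HRParams) -> np.ndarray:
    """Analytic 3x3 linearization of the vector field at ``state``."""
    return _kernels.jac(state.x, params.to_vector())


def integrate(
    params: HRParams,
    initial: State | tuple = DEFAULT_INITIAL,
    t_end: float = 1000.0,
    dt: float = DEFAULT_DT,
    seed: Optional[int] = None,
) -> Trajectory:
    """Integrate from ``initial`` over [0, t_end] at fixed step ``dt``.

    Deterministic runs use 4th-order Runge-Kutta; when
    ``params.noise_intensity > 0`` an Euler-Maruyama scheme adds white
    noise (scaled by sqrt(dt)) to dy/dt, or dx/dt if ``noise_on_x``.

    Raises
    ------
    IntegrationBlowUpError
        if the state leaves the finite range, naming the failure time.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t_end < 0:
        raise ValueError("t_end must be non-negative")
    state0 = initial.to_array() if isinstance(initial, State) else np.asarray(initial, float)
    n_steps = int(round(t_end / dt))
    p = params.to_vector()
    if params.noise_intensity > 0:
        if seed is None:
            seed = 0
        states, blow = _kernels.em_trajectory(
            state0, n_steps, dt, p, params.noise_intensity,
            params.noise_on_x, seed)
    else:
        states, blow = _kernels.rk4_trajectory(state0, n_steps, dt, p)
    if blow >= 0:
        raise IntegrationBlowUpError(time=blow * dt)
    times = np.arange(len(states)) * dt
    return Trajectory(times=times, states=states, params=params)


def detect_spikes(
    traj: Trajectory,
    threshold: float = DEFAULT_SPIKE_THRESHOLD,
    min_separation: float = DEFAULT_MIN_SEPARATION,
) -> SpikeTrain:
    """Spike times as interior local maxima of x at or above ``threshold``.

    Peak locations are refined by a quadratic fit through the three
    samples around each maximum; maxima closer than ``min_separation`` to
    the previous accepted spike are dropped.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    x = traj.x
    t = traj.times
    if len(x) < 3:
        return SpikeTrain(np.empty(0))
    dt = t[1] - t[0]
    mid = x[1:-1]
    is_peak = (mid >= threshold) & (mid > x[:-2]) & (mid >= x[2:])
    idx = np.nonzero(is_peak)[0] + 1
    out = []
    last = -np.inf
    for i in idx:
        t_spike = _kernels._refine_peak(t[i], dt, x[i - 1], x[i], x[i + 1])
        if t_spike - last >= min_separation:
            out.append(t_spike)
            last = t_spike
    return SpikeTrain(np.array(out))


def isis_from_spikes(train: SpikeTrain) -> ISISeries:
    """Successive differences of spike times."""
    if len(train) < 2:
        raise InsufficientSpikesError(
            f"need at least 2 spikes to form ISIs, got {len(train)}")
    times = train.spike_times
    return ISISeries(isis=np.diff(times), units=train.units,
                     origin_times=times[1:].copy())


def simulate_isis(
    params: HRParams,
    n_isis: Optional[int] = None,
    t_end: float = 5000.0,
    dt: float = DEFAULT_DT,
    transient: float = DEFAULT_TRANSIENT,
    threshold: float = DEFAULT_SPIKE_THRESHOLD,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    initial: State | tuple = DEFAULT_INITIAL,
    seed: Optional[int] = None,
    return_final_state: bool = False,
):
    """Integrate and return post-transient ISIs without storing the path.

    If ``n_isis`` is given, integration is extended (up to 20x ``t_end``)
    until that many ISIs are collected.  The combined integrate/detect
    kernel keeps memory flat for long runs and parameter scans.
    """
    state0 = initial.to_array() if isinstance(initial, State) else np.asarray(initial, float)
    p = params.to_vector()
    t_total = t_end
    while True:
        max_spikes = int(t_total / min_separation) + 16
        if params.noise_intensity > 0:
            times, final, blow = _kernels.em_spike_times(
                state0, t_total, dt, p, params.noise_intensity,
                params.noise_on_x, 0 if seed is None else seed,
                threshold, min_separation, transient, max_spikes)
        else:
            times, final, blow = _kernels.rk4_spike_times(
                state0, t_total, dt, p, threshold, min_separation,
                transient, max_spikes)
        if blow >= 0:
            raise IntegrationBlowUpError(time=blow)
        if n_isis is None or len(times) - 1 >= n_isis or t_total >= 20 * t_end:
            break
        t_total *= 2
    train = SpikeTrain(times)
    if len(times) < 2:
        isis = ISISeries(np.empty(0))
    else:
        isis = isis_from_spikes(train)
        if n_isis is not None and len(isis) > n_isis:
            isis = ISISeries(isis.isis[:n_isis], units=isis.units,
                             origin_times=isis.origin_times[:n_isis])
    if return_final_state:
        return isis, State.from_array(final)
    return isis


def largest_lyapunov(
    params: HRParams,
    t_transient: float = 500.0,
    t_average: float = 5000.0,
    renorm_interval: float = 1.0,
    dt: float = DEFAULT_DT,
    initial: State | tuple = DEFAULT_INITIAL,
    tangent: tuple = (1.0, 0.0, 0.0),
    return_final_state: bool = False,
):
    """Largest Lyapunov exponent by the Benettin tangent-vector method.

    A unit tangent vector is advanced under the variational equations
    alongside the trajectory and renormalized every ``renorm_interval``
    time units; the exponent is the mean log stretch factor per unit
    time, accumulated over ``t_average`` after discarding ``t_transient``.
    Only defined for the deterministic model.
    """
    if params.noise_intensity > 0:
        raise ValueError("Lyapunov exponent is defined for the noiseless model only")
    if t_average < 100 * renorm_interval:
        raise ValueError("t_average must cover at least 100 renormalizations")
    state0 = initial.to_array() if isinstance(initial, State) else np.asarray(initial, float)
    lle, final, blow = _kernels.benettin_lle(
        state0, np.asarray(tangent, float), dt, t_transient, t_average,
        renorm_interval, params.to_vector())
    if blow >= 0:
        raise IntegrationBlowUpError(time=blow)
    if return_final_state:
        return lle, State.from_array(final)
    return lle
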