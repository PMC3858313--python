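"""Compiled inner loops for the Hindmarsh-Rose integrator.

All kernels take the model constants as a flat float64 vector
``p = [a, b, c, d, s, x_rest, r, I]`` and operate on raw arrays so that
numba can compile them once and the high-level API stays pure Python.
"""

import numpy as np
from numba import njit

# indices into the parameter vector
A, B, C, D, S, XR, R, I_EXT = 0, 1, 2, 3, 4, 5, 6, 7


@njit(cache=True)
def deriv(x, y, z, p):
    dx = y - p[A] * x ** 3 + p[B] * x ** 2 - z + p[I_EXT]
    dy = p[C] - p[D] * x ** 2 - y
    dz = p[R] * (p[S] * (x - p[XR]) - z)
    return dx, dy, dz


@njit(cache=True)
def rk4_step(x, y, z, dt, p):
    k1x, k1y, k1z = deriv(x, y, z, p)
    k2x, k2y, k2z = deriv(x + 0.5 * dt * k1x, y + 0.5 * dt * k1y, z + 0.5 * dt * k1z, p)
    k3x, k3y, k3z = deriv(x + 0.5 * dt * k2x, y + 0.5 * dt * k2y, z + 0.5 * dt * k2z, p)
    k4x, k4y, k4z = deriv(x + dt * k3x, y + dt * k3y, z + dt * k3z, p)
    x += dt / 6.0 * (k1x + 2.0 * k2x + 2.0 * k3x + k4x)
    y += dt / 6.0 * (k1y + 2.0 * k2y + 2.0 * k3y + k4y)
    z += dt / 6.0 * (k1z + 2.0 * k2z + 2.0 * k3z + k4z)
    return x, y, z


@njit(cache=True)
def rk4_trajectory(state0, n_steps, dt, p):
    """Integrate the deterministic model, storing every sample.

    Returns (states, blowup_step); blowup_step is -1 on success, else the
    first step index at which the state became non-finite (the trajectory
    is truncated there).
    """
    out = np.empty((n_steps + 1, 3))
    x, y, z = state0[0], state0[1], state0[2]
    out[0, 0], out[0, 1], out[0, 2] = x, y, z
    for i in range(1, n_steps + 1):
        x, y, z = rk4_step(x, y, z, dt, p)
        if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
            return out[:i], i
        out[i, 0], out[i, 1], out[i, 2] = x, y, z
    return out, -1


@njit(cache=True)
def em_trajectory(state0, n_steps, dt, p, sigma, noise_on_x, seed):
    """Euler-Maruyama integration with additive white noise.

    The noise term of intensity ``sigma`` enters dy/dt (default) or dx/dt
    when ``noise_on_x`` is true, scaled by sqrt(dt).
    """
    np.random.seed(seed)
    out = np.empty((n_steps + 1, 3))
    x, y, z = state0[0], state0[1], state0[2]
    out[0, 0], out[0, 1], out[0, 2] = x, y, z
    sq = np.sqrt(dt)
    for i in range(1, n_steps + 1):
        dx, dy, dz = deriv(x, y, z, p)
        w = sigma * sq * np.random.normal()
        if noise_on_x:
            x += dt * dx + w
            y += dt * dy
        else:
            x += dt * dx
            y += dt * dy + w
        z += dt * dz
        if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
            return out[:i], i
        out[i, 0], out[i, 1], out[i, 2] = x, y, z
    return out, -1


@njit(cache=True)
def _push_spike(times, n, t_spike, min_sep):
    """Append a refined spike time if it clears the refractory floor."""
    if n == 0 or t_spike - times[n - 1] >= min_sep:
        if n < times.shape[0]:
            times[n] = t_spike
            n += 1
    return n


@njit(cache=True)
def _refine_peak(t_mid, dt, x0, x1, x2):
    denom = x0 - 2.0 * x1 + x2
    if denom >= 0.0:  # flat or degenerate; keep the sample time
        return t_mid
    off = 0.5 * (x0 - x2) / denom * dt
    if off > dt:
        off = dt
    elif off < -dt:
        off = -dt
    return t_mid + off


@njit(cache=True)
def rk4_spike_times(state0, t_end, dt, p, threshold, min_sep, t_discard, max_spikes):
    """Integrate without storing the trajectory; return refined spike times.

    Spikes are interior local maxima of x at or above ``threshold``;
    their location is refined by a quadratic fit through the three samples
    around the peak. Maxima before ``t_discard`` are skipped.
    Returns (spike_times, final_state, blowup_time); blowup_time is -1.0
    on success.
    """
    times = np.empty(max_spikes)
    n = 0
    x, y, z = state0[0], state0[1], state0[2]
    n_steps = int(np.round(t_end / dt))
    xm2 = x
    xm1 = x
    for i in range(1, n_steps + 1):
        x, y, z = rk4_step(x, y, z, dt, p)
        if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
            final = np.array([x, y, z])
            return times[:n], final, i * dt
        if i >= 2:
            t_mid = (i - 1) * dt
            if xm1 >= threshold and xm1 > xm2 and xm1 >= x and t_mid >= t_discard:
                t_spike = _refine_peak(t_mid, dt, xm2, xm1, x)
                n = _push_spike(times, n, t_spike, min_sep)
        xm2 = xm1
        xm1 = x
    final = np.array([x, y, z])
    return times[:n], final, -1.0


@njit(cache=True)
def em_spike_times(state0, t_end, dt, p, sigma, noise_on_x, seed,
                   threshold, min_sep, t_discard, max_spikes):
    """Noisy counterpart of :func:`rk4_spike_times` (Euler-Maruyama)."""
    np.random.seed(seed)
    times = np.empty(max_spikes)
    n = 0
    x, y, z = state0[0], state0[1], state0[2]
    n_steps = int(np.round(t_end / dt))
    sq = np.sqrt(dt)
    xm2 = x
    xm1 = x
    for i in range(1, n_steps + 1):
        dx, dy, dz = deriv(x, y, z, p)
        w = sigma * sq * np.random.normal()
        if noise_on_x:
            x += dt * dx + w
            y += dt * dy
        else:
            x += dt * dx
            y += dt * dy + w
        z += dt * dz
        if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
            final = np.array([x, y, z])
            return times[:n], final, i * dt
        if i >= 2:
            t_mid = (i - 1) * dt
            if xm1 >= threshold and xm1 > xm2 and xm1 >= x and t_mid >= t_discard:
                t_spike = _refine_peak(t_mid, dt, xm2, xm1, x)
                n = _push_spike(times, n, t_spike, min_sep)
        xm2 = xm1
        xm1 = x
    final = np.array([x, y, z])
    return times[:n], final, -1.0


@njit(cache=True)
def jac(x, p):
    """Analytic Jacobian of the vector field at membrane potential x."""
    J = np.empty((3, 3))
    J[0, 0] = -3.0 * p[A] * x ** 2 + 2.0 * p[B] * x
    J[0, 1] = 1.0
    J[0, 2] = -1.0
    J[1, 0] = -2.0 * p[D] * x
    J[1, 1] = -1.0
    J[1, 2] = 0.0
    J[2, 0] = p[R] * p[S]
    J[2, 1] = 0.0
    J[2, 2] = -p[R]
    return J


@njit(cache=True)
def _tangent_rhs(x, v, p):
    dv0 = (-3.0 * p[A] * x ** 2 + 2.0 * p[B] * x) * v[0] + v[1] - v[2]
    dv1 = -2.0 * p[D] * x * v[0] - v[1]
    dv2 = p[R] * p[S] * v[0] - p[R] * v[2]
    return np.array([dv0, dv1, dv2])


@njit(cache=True)
def benettin_lle(state0, tangent0, dt, t_transient, t_average, renorm_interval, p):
    """Largest Lyapunov exponent by the Benettin tangent-vector method.

    State and a unit tangent vector are advanced together with RK4 (the
    variational equations use the Jacobian evaluated at the RK4 stage
    states); the tangent is renormalized every ``renorm_interval`` and the
    exponent is the mean log stretch per unit time after the transient.
    Returns (lle, final_state, blowup_time).
    """
    x, y, z = state0[0], state0[1], state0[2]
    n_tr = int(np.round(t_transient / dt))
    for _ in range(n_tr):
        x, y, z = rk4_step(x, y, z, dt, p)
        if not np.isfinite(x):
            return 0.0, np.array([x, y, z]), -2.0
    v = tangent0 / np.sqrt(tangent0[0] ** 2 + tangent0[1] ** 2 + tangent0[2] ** 2)
    steps_per_renorm = max(1, int(np.round(renorm_interval / dt)))
    n_renorm = int(np.round(t_average / (steps_per_renorm * dt)))
    log_sum = 0.0
    t_run = 0.0
    for _ in range(n_renorm):
        for _ in range(steps_per_renorm):
            # RK4 on the coupled (state, tangent) system
            k1x, k1y, k1z = deriv(x, y, z, p)
            k1v = _tangent_rhs(x, v, p)
            x2 = x + 0.5 * dt * k1x
            k2x, k2y, k2z = deriv(x2, y + 0.5 * dt * k1y, z + 0.5 * dt * k1z, p)
            k2v = _tangent_rhs(x2, v + 0.5 * dt * k1v, p)
            x3 = x + 0.5 * dt * k2x
            k3x, k3y, k3z = deriv(x3, y + 0.5 * dt * k2y, z + 0.5 * dt * k2z, p)
            k3v = _tangent_rhs(x3, v + 0.5 * dt * k2v, p)
            x4 = x + dt * k3x
            k4x, k4y, k4z = deriv(x4, y + dt * k3y, z + dt * k3z, p)
            k4v = _tangent_rhs(x4, v + dt * k3v, p)
            x += dt / 6.0 * (k1x + 2.0 * k2x + 2.0 * k3x + k4x)
            y += dt / 6.0 * (k1y + 2.0 * k2y + 2.0 * k3y + k4y)
            z += dt / 6.0 * (k1z + 2.0 * k2z + 2.0 * k3z + k4z)
            v = v + dt / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
            t_run += dt
            if not (np.isfinite(x) and np.isfinite(v[0])):
                return 0.0, np.array([x, y, z]), t_run
        norm = np.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
        if norm == 0.0:
            return -np.inf, np.array([x, y, z]), -1.0
        log_sum += np.log(norm)
        v /= norm
    lle = log_sum / (n_renorm * steps_per_renorm * dt)
    return lle, np.array([x, y, z]), -1.0


@njit(cache=True)
def drift_spike_times(state0, t_end, dt, p0, I_start, I_end, r_start, r_end,
                      exponential, tau, sigma, seed,
                      threshold, min_sep, t_discard, max_spikes):
    """Spike times while (I, r) drifts from start to end over [0, t_end].

    Linear profile: fraction = t/t_end.  Exponential approach:
    fraction = 1 - exp(-t/tau), rescaled so the end of the record reaches
    the line's end exactly.  Optional additive noise on dy (sigma > 0).
    Returns (spike_times, final_state, blowup_time).
    """
    np.random.seed(seed)
    p = p0.copy()
    times = np.empty(max_spikes)
    n = 0
    x, y, z = state0[0], state0[1], state0[2]
    n_steps = int(np.round(t_end / dt))
    sq = np.sqrt(dt)
    xm2 = x
    xm1 = x
    end_scale = 1.0 - np.exp(-t_end / tau) if exponential else 1.0
    for i in range(1, n_steps + 1):
        t = i * dt
        if exponential:
            frac = (1.0 - np.exp(-t / tau)) / end_scale
        else:
            frac = t / t_end
        p[I_EXT] = I_start + frac * (I_end - I_start)
        p[R] = r_start + frac * (r_end - r_start)
        if sigma > 0.0:
            dx, dy, dz = deriv(x, y, z, p)
            x += dt * dx
            y += dt * dy + sigma * sq * np.random.normal()
            z += dt * dz
        else:
            x, y, z = rk4_step(x, y, z, dt, p)
        if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
            final = np.array([x, y, z])
            return times[:n], final, t
        if i >= 2:
            t_mid = (i - 1) * dt
            if xm1 >= threshold and xm1 > xm2 and xm1 >= x and t_mid >= t_discard:
                t_spike = _refine_peak(t_mid, dt, xm2, xm1, x)
                n = _push_spike(times, n, t_spike, min_sep)
        xm2 = xm1
        xm1 = x
    final = np.array([x, y, z])
    return times[:n], final, -1.0
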