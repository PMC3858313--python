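"""Model core: vector field, Jacobian, integrator, spikes, Lyapunov exponent."""

import numpy as np
import pytest

from hrchaos import (
    HRParams,
    State,
    Trajectory,
    detect_spikes,
    hr_derivative,
    integrate,
    isis_from_spikes,
    jacobian,
    largest_lyapunov,
    simulate_isis,
)
from hrchaos.errors import InsufficientSpikesError, IntegrationBlowUpError

from conftest import CHAOTIC_POINT, PERIOD1_POINT


def test_derivative_closed_form_values():
    # At the origin with I = 0 only the constant terms survive.
    p = HRParams(I=0.0, r=0.0245)
    d = hr_derivative(State(0.0, 0.0, 0.0), p)
    assert d.x == pytest.approx(0.0)
    assert d.y == pytest.approx(1.0)          # c
    assert d.z == pytest.approx(0.0245 * 4.0 * 1.6)  # r*s*(0 - x_rest)

    # At (1, 0, 0): dx = -a + b + I, dy = c - d, dz = r*(s*(1 - x_rest)).
    p = HRParams(I=2.53, r=0.0245)
    d = hr_derivative(State(1.0, 0.0, 0.0), p)
    assert d.x == pytest.approx(-1.0 + 3.0 + 2.53)
    assert d.y == pytest.approx(1.0 - 5.0)
    assert d.z == pytest.approx(0.0245 * 4.0 * 2.6)


def test_derivative_honors_all_constants():
    p = HRParams(a=2.0, b=0.5, c=-1.0, d=3.0, s=2.0, x_rest=-1.0, r=0.1, I=1.5)
    st = State(0.7, -0.3, 0.2)
    d = hr_derivative(st, p)
    assert d.x == pytest.approx(-0.3 - 2.0 * 0.7**3 + 0.5 * 0.7**2 - 0.2 + 1.5)
    assert d.y == pytest.approx(-1.0 - 3.0 * 0.7**2 + 0.3)
    assert d.z == pytest.approx(0.1 * (2.0 * (0.7 + 1.0) - 0.2))


def test_jacobian_matches_finite_differences():
    p = HRParams(I=2.53, r=0.0245)
    st = np.array([0.4, -1.2, 2.9])
    J = jacobian(State(*st), p)
    eps = 1e-6
    J_fd = np.empty((3, 3))
    for j in range(3):
        hi, lo = st.copy(), st.copy()
        hi[j] += eps
        lo[j] -= eps
        f_hi = hr_derivative(State(*hi), p)
        f_lo = hr_derivative(State(*lo), p)
        J_fd[:, j] = (np.array([f_hi.x, f_hi.y, f_hi.z])
                      - np.array([f_lo.x, f_lo.y, f_lo.z])) / (2 * eps)
    np.testing.assert_allclose(J, J_fd, atol=1e-6)
    # trace has the closed form -3a x^2 + 2b x - 1 - r
    x = st[0]
    assert np.trace(J) == pytest.approx(-3 * x**2 + 6 * x - 1 - 0.0245)


def test_rk4_fourth_order_convergence():
    p = HRParams(**CHAOTIC_POINT)
    ref = integrate(p, t_end=20.0, dt=0.00125).states[-1]
    err = []
    for dt in (0.01, 0.005):
        err.append(np.linalg.norm(integrate(p, t_end=20.0, dt=dt).states[-1] - ref))
    # halving the step should shrink the error by roughly 2^4
    assert err[0] / err[1] > 8.0
    assert err[1] < 1e-8


def test_integration_reproducible_and_noise_seeded():
    p = HRParams(**CHAOTIC_POINT)
    a = integrate(p, t_end=100.0)
    b = integrate(p, t_end=100.0)
    np.testing.assert_array_equal(a.states, b.states)

    pn = HRParams(I=2.53, r=0.0245, noise_intensity=0.05)
    n1 = integrate(pn, t_end=100.0, seed=3)
    n2 = integrate(pn, t_end=100.0, seed=3)
    n3 = integrate(pn, t_end=100.0, seed=4)
    np.testing.assert_array_equal(n1.states, n2.states)
    assert not np.array_equal(n1.states, n3.states)
    # noise must actually perturb the deterministic path
    assert not np.array_equal(n1.states, a.states[: len(n1.states)])


def test_blowup_raises_with_time():
    p = HRParams(**CHAOTIC_POINT)
    with pytest.raises(IntegrationBlowUpError) as exc:
        integrate(p, initial=(1e6, 0.0, 0.0), t_end=10.0)
    assert exc.value.time >= 0.0


def test_detect_spikes_sine_oracle():
    dt = 0.01
    t = np.arange(0, 50, dt)
    period = 7.0
    x = np.sin(2 * np.pi * t / period)
    traj = Trajectory(times=t, states=np.column_stack([x, x, x]),
                      params=HRParams())
    train = detect_spikes(traj, threshold=0.0, min_separation=1.0)
    expected = np.arange(period / 4, 50, period)
    assert len(train) == len(expected)
    # quadratic refinement should beat the sampling grid comfortably
    np.testing.assert_allclose(train.spike_times, expected, atol=dt / 10)


def test_detect_spikes_threshold_and_separation():
    dt = 0.01
    t = np.arange(0, 30, dt)
    # tall peaks every 10 units plus sub-threshold ripple in between
    x = 1.0 * np.exp(-((t % 10) - 5) ** 2 / 0.1) - 0.5 + 0.3 * np.cos(2 * np.pi * t)
    traj = Trajectory(times=t, states=np.column_stack([x, x, x]), params=HRParams())
    train = detect_spikes(traj, threshold=0.2, min_separation=1.0)
    assert len(train) == 3
    # with a huge min_separation only the first survives
    train2 = detect_spikes(traj, threshold=0.2, min_separation=100.0)
    assert len(train2) == 1


def test_isis_from_spikes():
    from hrchaos import SpikeTrain

    isis = isis_from_spikes(SpikeTrain(np.array([1.0, 3.0, 3.5, 7.0])))
    np.testing.assert_allclose(isis.isis, [2.0, 0.5, 3.5])
    np.testing.assert_allclose(isis.origin_times, [3.0, 3.5, 7.0])
    with pytest.raises(InsufficientSpikesError):
        isis_from_spikes(SpikeTrain(np.array([1.0])))


def test_simulate_isis_collects_requested_count(chaotic_isis):
    assert len(chaotic_isis) == 520
    assert np.all(chaotic_isis.isis > 0)
    # extension loop: tiny t_end still yields the requested count
    p = HRParams(**PERIOD1_POINT)
    isis = simulate_isis(p, n_isis=50, t_end=600.0)
    assert len(isis) == 50


def test_simulate_isis_matches_integrate_then_detect():
    p = HRParams(**PERIOD1_POINT)
    traj = integrate(p, t_end=3000.0)
    train = detect_spikes(traj)
    post = train.spike_times[train.spike_times >= 500.0]
    direct = simulate_isis(p, t_end=3000.0)
    np.testing.assert_allclose(np.diff(post), direct.isis, rtol=0, atol=1e-9)


def test_lyapunov_sign_by_regime():
    chaotic = largest_lyapunov(HRParams(**CHAOTIC_POINT))
    periodic = largest_lyapunov(HRParams(**PERIOD1_POINT))
    quiescent = largest_lyapunov(HRParams(I=1.0, r=0.0245))
    assert chaotic > 0.001
    assert abs(periodic) < 0.002
    assert quiescent < 0.0


def test_lyapunov_tangent_direction_invariance():
    p = HRParams(**CHAOTIC_POINT)
    l1 = largest_lyapunov(p, tangent=(1.0, 0.0, 0.0))
    l2 = largest_lyapunov(p, tangent=(0.0, 1.0, 0.0))
    assert l2 == pytest.approx(l1, abs=0.003)


def test_lyapunov_rejects_noisy_params():
    with pytest.raises(ValueError):
        largest_lyapunov(HRParams(I=2.53, r=0.0245, noise_intensity=0.1))
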