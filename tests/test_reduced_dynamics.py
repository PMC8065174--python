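"""Polar/Kuramoto reductions, closed-form laws, and stability analysis."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

import doponet as dn
from doponet.reduced_dynamics import steady_radius_quadrature

SQRT8 = np.sqrt(8.0)


# ---------------------------------------------------------------------------
# Independent oracles (kept free of the package code paths they check)


def reduced_phase_frequency(P, omega0=1.0):
    """Rotation frequency of d(theta)/dt = omega0 + (P/sqrt(8)) sin(4 theta)
    measured by integrating the ODE through several revolutions."""
    n_rev = 8
    sol = solve_ivp(
        lambda t, th: omega0 + P / SQRT8 * np.sin(4 * th[0]),
        [0.0, 2000.0],
        [0.0],
        events=lambda t, th: th[0] - 2 * np.pi * n_rev,
        rtol=1e-11,
        atol=1e-12,
        max_step=0.5,
    )
    t_event = sol.t_events[0][0]
    return 2 * np.pi * n_rev / t_event


def period_by_quadrature(P, omega0=1.0):
    val, _ = quad(
        lambda th: 1.0 / (omega0 + P / SQRT8 * np.sin(4 * th)), -np.pi, np.pi
    )
    return val


# ---------------------------------------------------------------------------
# Coordinate transforms


@pytest.mark.parametrize(
    "v,w,theta,R",
    [(1.0, 0.0, 0.0, 1.0), (0.0, -2.0, -np.pi / 2, 4.0)],
)
def test_polar_transform_point_values(v, w, theta, R):
    traj = dn.Trajectory(
        times=np.array([0.0, 1.0]),
        v=np.array([[v, v]]),
        w=np.array([[w, w]]),
    )
    polar = dn.to_polar(traj)
    assert polar.theta[0, 0] == pytest.approx(theta, abs=1e-15)
    assert polar.R[0, 0] == pytest.approx(R, rel=1e-15)
    back = dn.from_polar(polar)
    np.testing.assert_allclose(back.v, traj.v, atol=1e-12)
    np.testing.assert_allclose(back.w, traj.w, atol=1e-12)


def test_polar_round_trip_random():
    rng = np.random.default_rng(12)
    times = np.linspace(0, 5, 40)
    v = rng.normal(scale=1.0, size=(4, 40))
    w = rng.normal(scale=1.0, size=(4, 40))
    v[np.abs(v) < 1e-3] = 1e-3  # keep R above the validity floor
    traj = dn.Trajectory(times=times, v=v, w=w)
    back = dn.from_polar(dn.to_polar(traj))
    np.testing.assert_allclose(back.v, v, atol=1e-12)
    np.testing.assert_allclose(back.w, w, atol=1e-12)


def test_to_polar_flags_underflow_samples():
    times = np.array([0.0, 1.0, 2.0])
    v = np.array([[1.0, 0.0, 1.0]])
    w = np.array([[0.0, 0.0, 0.0]])
    polar = dn.to_polar(dn.Trajectory(times=times, v=v, w=w))
    assert polar.theta_valid[0].tolist() == [True, False, True]
    assert np.isfinite(polar.theta[0, 1])  # carried forward, not NaN


def test_theta_unwrapped_continuously():
    params = dn.NeuronParams.from_tilde([1.0])
    config = dn.SimulationConfig(duration=60.0, seed=2)
    traj = dn.simulate(params, dn.NetworkCoupling.uncoupled(1), config)
    polar = dn.to_polar(traj.window(20.0))
    assert np.all(np.abs(np.diff(polar.theta[0])) < np.pi)
    assert polar.theta[0, -1] - polar.theta[0, 0] > 4 * np.pi


# ---------------------------------------------------------------------------
# Closed-form laws


def test_omega_closed_form_values():
    assert dn.omega_closed_form(0.0, 1.0) == 1.0
    assert dn.omega_closed_form(SQRT8, 1.0) == 0.0
    # independent oracle: direct integration of the reduced phase ODE
    oracle = reduced_phase_frequency(2.0)
    assert dn.omega_closed_form(2.0, 1.0) == pytest.approx(oracle, rel=1e-3)
    assert dn.omega_closed_form(2.0, 1.0) == pytest.approx(0.70711, abs=5e-6)
    with pytest.raises(ValueError):
        dn.omega_closed_form(-0.1, 1.0)
    with pytest.raises(ValueError):
        dn.omega_closed_form(3.0, 1.0)


def test_period_closed_form_values():
    assert dn.period_closed_form(0.0, 1.0) == pytest.approx(2 * np.pi, rel=1e-15)
    assert dn.period_closed_form(2.0, 1.0) == pytest.approx(
        period_by_quadrature(2.0), rel=1e-9
    )
    assert dn.period_closed_form(2.0, 1.0) == pytest.approx(8.8858, abs=1e-4)
    with pytest.raises(ValueError):
        dn.period_closed_form(SQRT8, 1.0)


@pytest.mark.parametrize("p_tilde", [0.1, 0.5, 1.0, 1.9, 2.5, 2.8])
def test_omega_period_identity(p_tilde):
    assert dn.omega_closed_form(p_tilde) * dn.period_closed_form(
        p_tilde
    ) == pytest.approx(2 * np.pi, rel=1e-12)


@pytest.mark.parametrize("p_tilde", [0.5, 1.0, 1.5, 2.0, 2.5])
def test_reduced_phase_ode_period_matches_closed_form(p_tilde):
    """Direct integration of the phase equation reproduces T(P) to 0.1%."""
    assert period_by_quadrature(p_tilde) == pytest.approx(
        dn.period_closed_form(p_tilde), rel=1e-3
    )


def test_steady_radius_values():
    assert dn.steady_radius(0.0) == 0.0
    assert dn.steady_radius(1.0) == pytest.approx(1.41421356, abs=1e-8)
    assert dn.steady_radius(-1.0) == 0.0
    for P in np.linspace(0.0, 10.0, 11):
        assert steady_radius_quadrature(P) == pytest.approx(
            dn.steady_radius(P), abs=1e-9
        )


# ---------------------------------------------------------------------------
# Reduced simulators


def test_polar_single_neuron_steady_law_and_rate():
    """Uncoupled polar neuron at P~ = 1: R hovers near sqrt(2) P and the
    rotation rate is within 2% of omega(P)."""
    params = dn.NeuronParams.from_tilde([1.0])
    config = dn.SimulationConfig(duration=300.0, record_stride=2, seed=3)
    polar = dn.simulate_polar(params, 0.0, config)
    late = polar.times > 100.0
    R_mean = np.mean(polar.R[0, late])
    assert R_mean == pytest.approx(np.sqrt(2.0), rel=0.08)
    rate = dn.detect_spikes(polar.window(75.0)).rates[0]
    assert rate == pytest.approx(dn.omega_closed_form(1.0), rel=0.02)


def test_polar_matches_cartesian_dynamics():
    """The polar equations are an exact rewrite of the Cartesian model:
    the measured rotation rates agree to integrator accuracy."""
    params = dn.NeuronParams.from_tilde([1.5])
    config = dn.SimulationConfig(duration=200.0, record_stride=2, seed=9)
    cart = dn.simulate(params, dn.NetworkCoupling.uncoupled(1), config)
    rate_cart = dn.detect_spikes(dn.to_polar(cart.window(50.0))).rates[0]
    polar = dn.simulate_polar(params, 0.0, config)
    rate_polar = dn.detect_spikes(polar.window(50.0)).rates[0]
    assert rate_polar == pytest.approx(rate_cart, rel=1e-3)


def test_polar_class_ii_rotator_limit():
    """P~ -> 0+: R stays tiny and d(theta)/dt ~ omega0 (pure rotator)."""
    params = dn.NeuronParams.from_tilde([0.01])
    config = dn.SimulationConfig(duration=100.0, seed=4)
    polar = dn.simulate_polar(params, 0.0, config)
    drift = (polar.theta[0, -1] - polar.theta[0, 0]) / (
        polar.times[-1] - polar.times[0]
    )
    assert drift == pytest.approx(1.0, rel=5e-3)


def test_kuramoto_identical_pair_locks():
    config = dn.SimulationConfig(duration=100.0, seed=5)
    polar = dn.simulate_kuramoto([1.0, 1.0], 0.1, config)
    dphi = polar.theta[0] - polar.theta[1]
    assert abs(dphi[-1]) < 1e-3


def test_kuramoto_uncoupled_pair_drifts_linearly():
    config = dn.SimulationConfig(duration=50.0, seed=5)
    polar = dn.simulate_kuramoto([1.0, 1.5], 0.0, config)
    dphi = polar.theta[1] - polar.theta[0]
    slope = (dphi[-1] - dphi[0]) / (polar.times[-1] - polar.times[0])
    assert slope == pytest.approx(0.5, rel=1e-9)


@pytest.mark.parametrize(
    "j_k,locks", [(0.55, True), (0.45, False)]
)
def test_kuramoto_adler_threshold(j_k, locks):
    """Two oscillators with |d omega| = 1 lock iff J_k > 0.5: the phase
    difference obeys d(Delta)/dt = 1 - 2 J_k sin(Delta) (Adler equation)."""
    config = dn.SimulationConfig(duration=300.0, seed=6)
    polar = dn.simulate_kuramoto(
        [1.0, 2.0], j_k, config, initial_phases=np.array([0.0, 0.1])
    )
    dphi = polar.theta[1] - polar.theta[0]
    late_drift = dphi[-1] - dphi[len(dphi) // 2]
    if locks:
        assert abs(late_drift) < 0.01
    else:
        assert late_drift > 2 * np.pi


# ---------------------------------------------------------------------------
# Stability


def test_linearize_origin_eigenvalues():
    eq = dn.linearize(0.5, 1.0, (0.0, 0.0))
    np.testing.assert_allclose(
        sorted(eq.eigenvalues, key=lambda z: z.imag), [0.5 - 1j, 0.5 + 1j]
    )
    assert eq.classification == "unstable-focus"
    assert dn.linearize(0.0, 1.0, (0.0, 0.0)).classification == "marginal"
    eq2 = dn.linearize(-1.0, 2.0, (0.0, 0.0))
    np.testing.assert_allclose(
        sorted(eq2.eigenvalues, key=lambda z: z.imag), [-1 - 2j, -1 + 2j]
    )
    assert eq2.classification == "stable-focus"


def test_linearize_rejects_non_equilibrium():
    with pytest.raises(ValueError, match="residual"):
        dn.linearize(0.5, 1.0, (0.3, 0.2))


def test_find_equilibria_below_threshold():
    report = dn.find_equilibria(-0.5)
    assert len(report.equilibria) == 1
    eq = report.equilibria[0]
    assert abs(eq.v) < 1e-9 and abs(eq.w) < 1e-9
    assert eq.classification == "stable-focus"


def test_find_equilibria_small_positive_pump():
    report = dn.find_equilibria(0.5)
    assert len(report.equilibria) == 1
    assert report.equilibria[0].classification == "unstable-focus"


def test_find_equilibria_beyond_snlc_edge():
    """P~ = 3 > sqrt(8): saddle-node pairs born on the limit cycle, at
    radius near the steady law and with real positive eigenvalues."""
    report = dn.find_equilibria(3.0)
    off_origin = [e for e in report.equilibria if np.hypot(e.v, e.w) > 1e-6]
    assert len(off_origin) == 8  # 4 saddle-node pairs (sin 4 theta symmetry)
    assert any(
        np.any((e.eigenvalues.real > 0) & (e.eigenvalues.imag == 0))
        for e in off_origin
    )
    for e in off_origin:
        R = e.v**2 + e.w**2
        assert 3.4 < R < 5.1  # near R ~ sqrt(2) P = 4.24


def test_snlc_threshold_value_and_scaling():
    assert dn.snlc_threshold(1.0) == pytest.approx(SQRT8, abs=1e-4)
    assert dn.snlc_threshold(2.0) == pytest.approx(
        2 * dn.snlc_threshold(1.0), rel=1e-3
    )


def test_below_snlc_threshold_rotation_persists():
    P = 0.99 * SQRT8
    params = dn.NeuronParams.from_tilde([P])
    config = dn.SimulationConfig(duration=150.0, seed=8)
    polar = dn.simulate_polar(params, 0.0, config)
    assert polar.theta[0, -1] - polar.theta[0, 0] > 2 * np.pi


def test_phase_diagram_quiescent_cell_and_serialization(tmp_path):
    config = dn.SimulationConfig(duration=60.0, record_stride=5, seed=10)
    diagram = dn.scan_phase_diagram((-1.0, -0.3), (0.0, 0.0), (4, 1), config)
    assert np.all(diagram.omega == 0.0)
    assert diagram.ah_boundary == [] and diagram.snlc_boundary == []
    from doponet.io import write_phase_diagram

    write_phase_diagram(diagram, tmp_path / "pd.csv", tmp_path / "pd.json")
    df = __import__("pandas").read_csv(tmp_path / "pd.csv")
    assert set(df["region"]) == {"quiescent"}
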