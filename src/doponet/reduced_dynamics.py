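"""Reduced models and bifurcation analysis for the paired-DOPO neuron.

In polar form, sqrt(R_i) e^{i theta_i} = v_i + i w_i, an all-to-all
network with uniform coupling J_k obeys

    dtheta_i/dt = omega0 - J_k sum_{j!=i} eps_ij sin(theta_i - theta_j)
                  + (R_i / 4) sin 4 theta_i
    dR_i/dt     = 2 P_i R_i + 2 J_k R_i sum_{j!=i} eps_ij cos(theta_i - theta_j)
                  - (R_i^2 / 2)(cos 4 theta_i + 3)

with eps_ij = sqrt(R_j / R_i).  The sin(4 theta) term is what turns the
class-II rotator into a class-I (saddle-node on limit cycle) unit as the
pump grows: at steady amplitude R = sqrt(2) P the phase obeys
dtheta/dt = omega0 + (P / sqrt(8)) sin 4 theta, giving the spiking
frequency omega(P) = omega0 sqrt(1 - P^2 / (8 omega0^2)) for
0 <= P/omega0 <= sqrt(8), with the SNLC edge at P* = sqrt(8) omega0.

This module also hosts a phase-only Kuramoto simulator used as the
reference model for synchronization tests, and linear-stability tooling
(Jacobian, equilibria, AH/SNLC phase diagram).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from .dopo_core import (
    IntegrationError,
    NeuronParams,
    SimulationConfig,
    Trajectory,
    initial_state,
)
from .schedules import Schedule, constant

__all__ = [
    "PolarTrajectory",
    "StabilityReport",
    "Equilibrium",
    "PhaseDiagram",
    "to_polar",
    "from_polar",
    "simulate_polar",
    "simulate_kuramoto",
    "omega_closed_form",
    "period_closed_form",
    "steady_radius",
    "steady_radius_quadrature",
    "linearize",
    "find_equilibria",
    "snlc_threshold",
    "scan_phase_diagram",
]

R_FLOOR = 1e-12


@dataclass
class PolarTrajectory:
    """Phase/squared-amplitude time series; theta is stored unwrapped."""

    times: np.ndarray
    theta: np.ndarray  # (n, T), unwrapped
    R: np.ndarray | None = None  # (n, T), R = v^2 + w^2; None for Kuramoto
    theta_valid: np.ndarray | None = None  # mask, False where R under-floor

    def __post_init__(self) -> None:
        if self.theta.shape[1] != len(self.times):
            raise ValueError("theta/time shape mismatch")
        if self.R is not None and self.R.shape != self.theta.shape:
            raise ValueError("R must match theta shape")

    @property
    def n_neurons(self) -> int:
        return self.theta.shape[0]

    def window(self, t0: float, t1: float | None = None) -> "PolarTrajectory":
        t1 = self.times[-1] if t1 is None else t1
        m = (self.times >= t0) & (self.times <= t1)
        return PolarTrajectory(
            times=self.times[m],
            theta=self.theta[:, m],
            R=None if self.R is None else self.R[:, m],
            theta_valid=None if self.theta_valid is None else self.theta_valid[:, m],
        )


@dataclass
class Equilibrium:
    v: float
    w: float
    jacobian: np.ndarray
    eigenvalues: np.ndarray
    classification: str  # stable-focus | unstable-focus | saddle | node | marginal


@dataclass
class StabilityReport:
    P: float
    i_ext: float
    omega0: float
    equilibria: list
    bifurcation: str = "none"  # AH | SNLC | none


@dataclass
class PhaseDiagram:
    """Spiking frequency over a (P~, I~_ext) grid plus bifurcation boundaries."""

    p_tilde: np.ndarray  # (nP,)
    i_tilde: np.ndarray  # (nI,)
    omega: np.ndarray  # (nI, nP); 0 marks quiescent cells
    ah_boundary: list = field(default_factory=list)  # [(P~, I~), ...]
    snlc_boundary: list = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        PP, II = np.meshgrid(self.p_tilde, self.i_tilde)
        return pd.DataFrame(
            {
                "p_tilde": PP.ravel(),
                "i_ext_tilde": II.ravel(),
                "omega_tilde": self.omega.ravel(),
                "region": np.where(self.omega.ravel() > 0, "spiking", "quiescent"),
            }
        )


# ---------------------------------------------------------------------------
# Coordinate transforms


def to_polar(traj: Trajectory, floor: float = R_FLOOR) -> PolarTrajectory:
    """Cartesian -> polar with continuous (unwrapped) phase.

    Where R falls below ``floor`` the phase is ill-defined; those samples
    carry the last defined value forward and are flagged in theta_valid.
    """
    R = traj.v**2 + traj.w**2
    valid = R >= floor
    theta = np.arctan2(traj.w, traj.v)
    out = np.empty_like(theta)
    for i in range(theta.shape[0]):
        th = theta[i].copy()
        ok = valid[i]
        if not ok.all():
            # hold the last defined angle through under-floor stretches
            last = th[ok][0] if ok.any() else 0.0
            for k in range(len(th)):
                if ok[k]:
                    last = th[k]
                else:
                    th[k] = last
        out[i] = np.unwrap(th)
    return PolarTrajectory(times=traj.times.copy(), theta=out, R=R, theta_valid=valid)


def from_polar(polar: PolarTrajectory) -> Trajectory:
    """Inverse of :func:`to_polar` (requires the amplitude channel)."""
    if polar.R is None:
        raise ValueError("cannot rebuild (v, w) without R")
    amp = np.sqrt(polar.R)
    return Trajectory(
        times=polar.times.copy(),
        v=amp * np.cos(polar.theta),
        w=amp * np.sin(polar.theta),
    )


# ---------------------------------------------------------------------------
# Reduced simulators


def simulate_polar(
    params: NeuronParams,
    j_k: float,
    config: SimulationConfig,
    initial: tuple[np.ndarray, np.ndarray] | None = None,
    pump_schedule: Schedule | None = None,
) -> PolarTrajectory:
    """Integrate the polar network equations with uniform all-to-all J_k.

    The amplitude-ratio weights eps_ij are recomputed every step from the
    current R; they are never stored.  R is floored at ``R_FLOOR`` (the
    phase of an empty oscillator is undefined, not singular).
    """
    n = params.n
    omega0 = params.omega0
    P_of = pump_schedule if pump_schedule is not None else constant(params.P)

    if initial is None:
        v0, w0 = initial_state(n, config.seed, config.init_noise_amplitude)
        theta = np.arctan2(w0, v0)
        R = np.maximum(v0**2 + w0**2, R_FLOOR)
    else:
        theta = np.array(initial[0], dtype=float).copy()
        R = np.array(initial[1], dtype=float).copy()
        if np.any(R <= 0):
            raise ValueError("initial R must be > 0")

    def rhs(t, th, R):
        Rc = np.maximum(R, R_FLOOR)
        P = np.broadcast_to(np.asarray(P_of(t), dtype=float), (n,))
        s = np.sqrt(Rc)
        C = np.sum(s * np.cos(th))
        S = np.sum(s * np.sin(th))
        # sum_j eps_ij sin(theta_i - theta_j); the j = i term vanishes
        sin_sum = (np.sin(th) * C - np.cos(th) * S) / s
        cos_sum = (np.cos(th) * C + np.sin(th) * S) / s - 1.0
        dth = omega0 - j_k * sin_sum + (Rc / 4.0) * np.sin(4.0 * th)
        dR = (
            2.0 * P * Rc
            + 2.0 * j_k * Rc * cos_sum
            - (Rc**2 / 2.0) * (np.cos(4.0 * th) + 3.0)
        )
        return dth, dR

    dt = config.dt
    n_steps = int(round(config.duration / dt))
    stride = config.record_stride
    rec_steps = list(range(0, n_steps + 1, stride))
    if rec_steps[-1] != n_steps:
        rec_steps.append(n_steps)
    rec_set = {k: idx for idx, k in enumerate(rec_steps)}

    T = len(rec_steps)
    times = np.array([k * dt for k in rec_steps])
    TH = np.empty((n, T))
    RR = np.empty((n, T))
    rk4 = config.method == "rk4"

    for k in range(n_steps + 1):
        if k in rec_set:
            idx = rec_set[k]
            TH[:, idx] = theta
            RR[:, idx] = R
            if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(R))):
                raise IntegrationError(
                    f"non-finite polar state at t={k * dt:.6g}; reduce dt"
                )
        if k == n_steps:
            break
        t = k * dt
        if rk4:
            k1t, k1r = rhs(t, theta, R)
            k2t, k2r = rhs(t + dt / 2, theta + dt / 2 * k1t, R + dt / 2 * k1r)
            k3t, k3r = rhs(t + dt / 2, theta + dt / 2 * k2t, R + dt / 2 * k2r)
            k4t, k4r = rhs(t + dt, theta + dt * k3t, R + dt * k3r)
            theta = theta + dt / 6 * (k1t + 2 * k2t + 2 * k3t + k4t)
            R = R + dt / 6 * (k1r + 2 * k2r + 2 * k3r + k4r)
        else:
            dth, dR = rhs(t, theta, R)
            theta = theta + dt * dth
            R = R + dt * dR
        R = np.maximum(R, R_FLOOR)

    valid = RR >= 10 * R_FLOOR
    return PolarTrajectory(times=times, theta=TH, R=RR, theta_valid=valid)


def simulate_kuramoto(
    omegas,
    j_k: float,
    config: SimulationConfig,
    initial_phases: np.ndarray | None = None,
) -> PolarTrajectory:
    """Phase-only all-to-all Kuramoto model,

        dtheta_i/dt = omega_i - J_k sum_j sin(theta_i - theta_j).

    Used as the reference model for synchronization behaviour.
    """
    omegas = np.atleast_1d(np.asarray(omegas, dtype=float))
    n = len(omegas)
    if initial_phases is None:
        rng = np.random.default_rng(config.seed)
        theta = rng.uniform(-np.pi, np.pi, size=n)
    else:
        theta = np.array(initial_phases, dtype=float).copy()

    def rhs(th):
        C = np.sum(np.cos(th))
        S = np.sum(np.sin(th))
        return omegas - j_k * (np.sin(th) * C - np.cos(th) * S)

    dt = config.dt
    n_steps = int(round(config.duration / dt))
    stride = config.record_stride
    rec_steps = list(range(0, n_steps + 1, stride))
    if rec_steps[-1] != n_steps:
        rec_steps.append(n_steps)
    rec_set = {k: idx for idx, k in enumerate(rec_steps)}
    times = np.array([k * dt for k in rec_steps])
    TH = np.empty((n, len(rec_steps)))
    rk4 = config.method == "rk4"

    for k in range(n_steps + 1):
        if k in rec_set:
            TH[:, rec_set[k]] = theta
        if k == n_steps:
            break
        if rk4:
            k1 = rhs(theta)
            k2 = rhs(theta + dt / 2 * k1)
            k3 = rhs(theta + dt / 2 * k2)
            k4 = rhs(theta + dt * k3)
            theta = theta + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        else:
            theta = theta + dt * rhs(theta)

    return PolarTrajectory(times=times, theta=TH, R=None)


# ---------------------------------------------------------------------------
# Closed-form laws


def omega_closed_form(P: float, omega0: float = 1.0) -> float:
    """Spiking angular frequency omega(P) = omega0 sqrt(1 - P^2/(8 omega0^2)).

    Valid on 0 <= P/omega0 <= sqrt(8); returns exactly 0 at the upper edge.
    """
    p_tilde = P / omega0
    if p_tilde < 0 or p_tilde > np.sqrt(8) * (1 + 1e-12):
        raise ValueError(f"P~ = {p_tilde:.6g} outside [0, sqrt(8)]")
    arg = max(0.0, 1.0 - P**2 / (8.0 * omega0**2))
    return omega0 * np.sqrt(arg)


def period_closed_form(P: float, omega0: float = 1.0) -> float:
    """Oscillation period T = 2 pi / sqrt(omega0^2 - P^2/8); diverges at the
    SNLC edge P = sqrt(8) omega0."""
    p_tilde = P / omega0
    if p_tilde < 0:
        raise ValueError("P must be >= 0")
    if p_tilde >= np.sqrt(8):
        raise ValueError("period diverges for P~ >= sqrt(8)")
    return 2.0 * np.pi / np.sqrt(omega0**2 - P**2 / 8.0)


def steady_radius(P: float) -> float:
    """Steady squared amplitude R = sqrt(2) P of a spiking neuron.

    The photon number (proportional to R = v^2 + w^2) grows linearly with
    pump.  P < 0 is below threshold: returns 0.
    """
    if P < 0:
        return 0.0
    return np.sqrt(2.0) * P


def steady_radius_quadrature(P: float) -> float:
    """Independent evaluation of the steady amplitude via the angular
    average (2P/pi) * integral_{-pi}^{pi} dtheta / (3 + cos 4 theta)."""
    if P < 0:
        return 0.0
    val, _ = integrate.quad(lambda th: 1.0 / (3.0 + np.cos(4.0 * th)), -np.pi, np.pi)
    return 2.0 * P / np.pi * val


# ---------------------------------------------------------------------------
# Linear stability


_MARGINAL_TOL = 1e-9


def _classify(eigs: np.ndarray) -> str:
    re = eigs.real
    im = eigs.imag
    if np.max(np.abs(re)) < _MARGINAL_TOL or np.any(np.abs(re) < _MARGINAL_TOL):
        return "marginal"
    if np.any(np.abs(im) > 0):
        return "stable-focus" if re[0] < 0 else "unstable-focus"
    if re[0] * re[1] < 0:
        return "saddle"
    return "node"


def _single_neuron_rhs(v: float, w: float, P: float, i_ext: float, omega0: float):
    return (
        P * v - v**3 - omega0 * w + i_ext,
        P * w - w**3 + omega0 * v,
    )


def linearize(
    P: float,
    omega0: float,
    equilibrium: tuple[float, float],
    i_ext: float = 0.0,
    residual_tol: float = 1e-8,
) -> Equilibrium:
    """Jacobian and eigenvalues at a single-neuron equilibrium.

    M = [[P - 3 v_e^2, -omega0], [omega0, P - 3 w_e^2]]; for the origin
    this gives lambda = P +/- i omega0 in closed form.
    """
    ve, we = equilibrium
    fv, fw = _single_neuron_rhs(ve, we, P, i_ext, omega0)
    res = float(np.hypot(fv, fw))
    if res > residual_tol:
        raise ValueError(
            f"({ve}, {we}) is not an equilibrium: residual {res:.3e}"
        )
    M = np.array([[P - 3 * ve**2, -omega0], [omega0, P - 3 * we**2]])
    # exact 2x2 eigenvalues
    tr = M[0, 0] + M[1, 1]
    det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
    disc = tr * tr / 4.0 - det
    if disc >= 0:
        rt = np.sqrt(disc)
        eigs = np.array([tr / 2.0 + rt, tr / 2.0 - rt], dtype=complex)
    else:
        rt = np.sqrt(-disc)
        eigs = np.array([tr / 2.0 + 1j * rt, tr / 2.0 - 1j * rt])
    return Equilibrium(
        v=float(ve),
        w=float(we),
        jacobian=M,
        eigenvalues=eigs,
        classification=_classify(eigs),
    )


def find_equilibria(
    P: float,
    i_ext: float = 0.0,
    omega0: float = 1.0,
    grid_points: int = 9,
    merge_tol: float = 1e-6,
) -> StabilityReport:
    """All real equilibria of the single-neuron cubic system.

    Deterministic multi-start root finding: seeds on a uniform grid over
    [-b, b]^2 with b = 3 sqrt(1 + |P|) (the cubic nullclines confine all
    equilibria to this box), polished by scipy's hybr solver, deduplicated
    within ``merge_tol``.
    """
    b = 3.0 * np.sqrt(1.0 + abs(P))
    seeds = np.linspace(-b, b, grid_points)
    found: list[tuple[float, float]] = []

    def fun(x):
        return _single_neuron_rhs(x[0], x[1], P, i_ext, omega0)

    for v0 in seeds:
        for w0 in seeds:
            sol = optimize.root(fun, [v0, w0], method="hybr", tol=1e-12)
            if not sol.success:
                continue
            ve, we = sol.x
            if np.hypot(*fun(sol.x)) > 1e-9:
                continue
            if any(np.hypot(ve - a, we - c) < merge_tol for a, c in found):
                continue
            found.append((float(ve), float(we)))

    found.sort(key=lambda p: (round(p[0], 9), round(p[1], 9)))
    eqs = [linearize(P, omega0, eq, i_ext=i_ext, residual_tol=1e-7) for eq in found]

    bifurcation = "none"
    for eq in eqs:
        if eq.classification == "marginal":
            bifurcation = "AH" if np.any(np.abs(eq.eigenvalues.imag) > 0) else "SNLC"
    return StabilityReport(
        P=P, i_ext=i_ext, omega0=omega0, equilibria=eqs, bifurcation=bifurcation
    )


def snlc_threshold(omega0: float = 1.0, tol: float = 1e-6) -> float:
    """Critical pump P* above which the uncoupled polar system has an
    equilibrium with R > 0 (spiking ceases: saddle-node on the cycle).

    Found by bisection on equilibrium existence.  A fixed point with
    R = 4P/(3 + cos 4 theta) > 0 exists iff
    min_theta [omega0 + P sin 4 theta / (3 + cos 4 theta)] <= 0.
    Analytically P* = sqrt(8) omega0; the bisection is kept independent of
    that closed form.
    """
    if not omega0 > 0:
        raise ValueError("omega0 must be > 0")

    th = np.linspace(-np.pi, np.pi, 4097)
    shape = np.sin(4 * th) / (3.0 + np.cos(4 * th))

    def has_equilibrium(P: float) -> bool:
        g = omega0 + P * shape
        if np.min(g) <= 0:
            return True
        # refine around the grid minimum
        k = int(np.argmin(g))
        lo, hi = th[max(k - 1, 0)], th[min(k + 1, len(th) - 1)]
        res = optimize.minimize_scalar(
            lambda x: omega0 + P * np.sin(4 * x) / (3.0 + np.cos(4 * x)),
            bounds=(lo, hi),
            method="bounded",
        )
        return res.fun <= 0

    lo, hi = 0.0, 4.0 * omega0
    if not has_equilibrium(hi):
        raise RuntimeError("bisection bracket failure: no equilibrium at P=4*omega0")
    while hi - lo > tol * omega0:
        mid = 0.5 * (lo + hi)
        if has_equilibrium(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Phase diagram


def scan_phase_diagram(
    p_tilde_range: tuple[float, float] = (-0.5, 3.5),
    i_tilde_range: tuple[float, float] = (0.0, 0.0),
    resolution: tuple[int, int] = (25, 1),
    config: SimulationConfig | None = None,
    omega0: float = 1.0,
    rate_floor: float = 1e-3,
) -> PhaseDiagram:
    """Spiking-frequency map over (P~, I~_ext) with AH/SNLC boundaries.

    Every grid cell is an uncoupled neuron, so the whole grid is simulated
    as one vectorized run.  The frequency is measured from the last 75% of
    the trajectory (transient discarded); boundary segments between a
    spiking and a quiescent cell are classified from the quiescent cell's
    equilibria: only foci -> AH side, any real-eigenvalue equilibrium
    (saddle/node pair born on the cycle) -> SNLC side.
    """
    from .observables import detect_spikes  # local import to avoid a cycle

    if config is None:
        config = SimulationConfig(dt=0.01, duration=200.0, record_stride=5)
    nP, nI = resolution
    p_grid = np.linspace(*p_tilde_range, nP)
    i_grid = np.linspace(*i_tilde_range, nI)
    PP, II = np.meshgrid(p_grid, i_grid)  # (nI, nP)

    params = NeuronParams.from_tilde(PP.ravel(), II.ravel())
    from .dopo_core import NetworkCoupling, simulate

    traj = simulate(params, NetworkCoupling.uncoupled(params.n), config)
    steady = to_polar(traj.window(0.25 * config.duration))
    rates = detect_spikes(steady).rates
    omega = np.where(np.abs(rates) > rate_floor, np.abs(rates), 0.0).reshape(PP.shape)

    spiking = omega > 0
    ah, snlc = [], []

    def classify_boundary(iq, jq):
        """Side of the quiescent cell (iq, jq) of a spiking/quiescent edge."""
        rep = find_equilibria(
            P=p_grid[jq] * omega0, i_ext=i_grid[iq] * omega0**1.5, omega0=omega0
        )
        real_eq = any(
            np.all(np.abs(eq.eigenvalues.imag) == 0) for eq in rep.equilibria
        )
        return "SNLC" if (real_eq and len(rep.equilibria) > 1) else "AH"

    for i in range(nI):
        for j in range(nP):
            for di, dj in ((0, 1), (1, 0)):
                i2, j2 = i + di, j + dj
                if i2 >= nI or j2 >= nP:
                    continue
                if spiking[i, j] == spiking[i2, j2]:
                    continue
                (iq, jq) = (i, j) if not spiking[i, j] else (i2, j2)
                mid = (
                    0.5 * (p_grid[j] + p_grid[j2]),
                    0.5 * (i_grid[i] + i_grid[i2]),
                )
                (ah if classify_boundary(iq, jq) == "AH" else snlc).append(mid)

    return PhaseDiagram(
        p_tilde=p_grid, i_tilde=i_grid, omega=omega, ah_boundary=ah, snlc_boundary=snlc
    )
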