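"""Full Cartesian dynamics of networks of paired-DOPO spiking neurons.

Each artificial neuron is a pair of degenerate optical parametric
oscillators whose in-phase amplitudes (v, w) obey

    dv_i/dt = P_i v_i - v_i^3 + J_vw w_i + gamma  * sum_j J_ij v_j + I_ext,i
    dw_i/dt = P_i w_i - w_i^3 + J_wv v_i + gamma' * sum_j J_ij w_j

with P_i = -1 + p_i the pump above oscillation threshold.  Antisymmetric
internal coupling (J_vw J_wv < 0) makes the pair rotate in the v-w plane
at the natural angular frequency omega0 = sqrt(-J_vw J_wv); the rotation is
the "spike".  With the default J_vw = -1, J_wv = +1 the phase
theta = arg(v + i w) advances at +omega0 near threshold.

Everything here is deterministic given the seed: randomness only enters
through the initial condition, drawn as i.i.d. zero-mean Gaussian noise
emulating growth from amplified vacuum fluctuations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .schedules import Schedule, TabulatedSchedule, constant

__all__ = [
    "NeuronParams",
    "NetworkCoupling",
    "SimulationConfig",
    "Trajectory",
    "IntegrationError",
    "initial_state",
    "simulate",
    "simulate_with_schedules",
]


class IntegrationError(RuntimeError):
    """Raised when the state leaves the finite range during integration."""


def _as_pernode(x, n: int, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError(f"{name} must be scalar or shape ({n},), got {arr.shape}")
    return arr


@dataclass
class NeuronParams:
    """Per-neuron pump/bias and the internal v-w coupling pair.

    ``pump`` is the raw pump amplitude p_i; the effective gain is
    P_i = -1 + p_i.  Dimensionless (tilde) forms divide by powers of
    omega0: P~ = P/omega0, I~_ext = I_ext / omega0**(3/2).
    """

    n: int
    pump: np.ndarray  # p_i
    i_ext: np.ndarray
    j_vw: float = -1.0
    j_wv: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("need at least one neuron")
        self.pump = _as_pernode(self.pump, self.n, "pump")
        self.i_ext = _as_pernode(self.i_ext, self.n, "i_ext")
        if not self.j_vw * self.j_wv < 0:
            raise ValueError(
                "internal coupling must be antisymmetric: J_vw * J_wv < 0"
            )

    @property
    def omega0(self) -> float:
        return float(np.sqrt(-self.j_vw * self.j_wv))

    @property
    def P(self) -> np.ndarray:
        """Pump above threshold, P_i = -1 + p_i."""
        return self.pump - 1.0

    @property
    def P_tilde(self) -> np.ndarray:
        return self.P / self.omega0

    @property
    def i_ext_tilde(self) -> np.ndarray:
        return self.i_ext / self.omega0**1.5

    @classmethod
    def from_tilde(
        cls,
        p_tilde,
        i_ext_tilde=0.0,
        n: int | None = None,
        j_vw: float = -1.0,
        j_wv: float = 1.0,
    ) -> "NeuronParams":
        """Build from dimensionless pump P~ and bias I~_ext."""
        omega0 = float(np.sqrt(-j_vw * j_wv))
        p_tilde = np.atleast_1d(np.asarray(p_tilde, dtype=float))
        if n is None:
            n = len(p_tilde)
        pump = 1.0 + _as_pernode(p_tilde, n, "p_tilde") * omega0
        i_ext = _as_pernode(i_ext_tilde, n, "i_ext_tilde") * omega0**1.5
        return cls(n=n, pump=pump, i_ext=i_ext, j_vw=j_vw, j_wv=j_wv)


@dataclass
class NetworkCoupling:
    """Symmetric synaptic matrix J with separate scalings for v and w."""

    n: int
    J: np.ndarray
    gamma: float = 0.0
    gamma_prime: float = 0.0

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=float)
        if self.J.shape != (self.n, self.n):
            raise ValueError(f"J must be {self.n}x{self.n}")
        if not np.all(np.isfinite(self.J)):
            raise ValueError("J must be finite")
        if not np.allclose(self.J, self.J.T, atol=1e-12):
            raise ValueError("J must be symmetric")
        if np.any(np.diag(self.J) != 0):
            raise ValueError("J must have zero diagonal")
        if not (np.isfinite(self.gamma) and np.isfinite(self.gamma_prime)):
            raise ValueError("gamma, gamma' must be finite")

    @classmethod
    def uncoupled(cls, n: int) -> "NetworkCoupling":
        return cls(n=n, J=np.zeros((n, n)), gamma=0.0, gamma_prime=0.0)

    def quantized(self, bits: int = 8) -> "NetworkCoupling":
        """Optional fixed-point rounding of J, mirroring finite-resolution
        feedback hardware.  Off the default code path."""
        scale = np.max(np.abs(self.J))
        if scale == 0:
            return self
        levels = 2 ** (bits - 1) - 1
        Jq = np.round(self.J / scale * levels) / levels * scale
        return replace(self, J=Jq)


@dataclass
class SimulationConfig:
    """Fixed-step integration settings (time in units of 1/omega0)."""

    dt: float = 1e-2
    duration: float = 100.0
    method: str = "rk4"  # or "euler"
    record_stride: int = 1
    seed: int = 0
    init_noise_amplitude: float = 1e-3

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if not self.duration >= self.dt:
            raise ValueError("duration must be >= dt")
        if self.method not in ("rk4", "euler"):
            raise ValueError("method must be 'rk4' or 'euler'")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")
        if self.init_noise_amplitude < 0:
            raise ValueError("init_noise_amplitude must be >= 0")


@dataclass
class Trajectory:
    """Recorded (v, w) time series plus the schedules actually applied."""

    times: np.ndarray  # (T,)
    v: np.ndarray  # (n, T)
    w: np.ndarray  # (n, T)
    pump: np.ndarray | None = None  # P_i(t) on the recorded grid, (n, T)
    bias: np.ndarray | None = None  # I_ext,i(t), (n, T)

    def __post_init__(self) -> None:
        if self.v.shape != self.w.shape or self.v.shape[1] != len(self.times):
            raise ValueError("inconsistent trajectory shapes")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_neurons(self) -> int:
        return self.v.shape[0]

    def final_state(self) -> tuple[np.ndarray, np.ndarray]:
        return self.v[:, -1].copy(), self.w[:, -1].copy()

    def window(self, t0: float, t1: float | None = None) -> "Trajectory":
        """Restrict to recorded samples with t0 <= t <= t1."""
        t1 = self.times[-1] if t1 is None else t1
        m = (self.times >= t0) & (self.times <= t1)
        return Trajectory(
            times=self.times[m],
            v=self.v[:, m],
            w=self.w[:, m],
            pump=None if self.pump is None else self.pump[:, m],
            bias=None if self.bias is None else self.bias[:, m],
        )

    def to_dataframe(self) -> pd.DataFrame:
        n, T = self.v.shape
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, n),
                "neuron": np.tile(np.arange(n), T),
                "v": self.v.T.ravel(),
                "w": self.w.T.ravel(),
            }
        )


def initial_state(
    n: int, seed: int, amplitude: float
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded i.i.d. Gaussian initial condition.

    Neuron i draws from its own substream ``default_rng([seed, i])`` so an
    n-neuron uncoupled run reproduces n independent single-neuron runs.
    """
    v0 = np.empty(n)
    w0 = np.empty(n)
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        v0[i], w0[i] = amplitude * rng.standard_normal(2)
    return v0, w0


def _check_schedule(sched: Schedule, duration: float) -> None:
    if isinstance(sched, TabulatedSchedule):
        lo, hi = sched.coverage()
        if lo > 0 or hi < duration:
            raise ValueError(
                f"schedule covers [{lo}, {hi}] but run needs [0, {duration}]"
            )


def simulate(
    params: NeuronParams,
    coupling: NetworkCoupling,
    config: SimulationConfig,
    initial: tuple[np.ndarray, np.ndarray] | None = None,
    pump_schedule: Schedule | None = None,
    bias_schedule: Schedule | None = None,
) -> Trajectory:
    """Integrate the Cartesian network ODEs with a fixed-step scheme.

    ``pump_schedule`` (if given) yields P_i(t) = -1 + p_i(t) and overrides
    ``params.P``; likewise ``bias_schedule`` overrides ``params.i_ext``.
    """
    n = params.n
    if coupling.n != n:
        raise ValueError(
            f"coupling is for {coupling.n} neurons, params for {n}"
        )

    P_of = pump_schedule if pump_schedule is not None else constant(params.P)
    I_of = bias_schedule if bias_schedule is not None else constant(params.i_ext)
    for sched in (P_of, I_of):
        _check_schedule(sched, config.duration)

    jvw, jwv = params.j_vw, params.j_wv
    J = coupling.J
    g, gp = coupling.gamma, coupling.gamma_prime
    use_J = (g != 0.0 or gp != 0.0) and np.any(J)

    def make_pernode(f):
        from .schedules import ConstantSchedule

        if isinstance(f, ConstantSchedule):
            cached = _as_pernode(f.value, n, "schedule value")
            return lambda t: cached
        return lambda t: _as_pernode(f(t), n, "schedule value")

    pernode_P = make_pernode(P_of)
    pernode_I = make_pernode(I_of)

    def rhs(t, v, w):
        P = pernode_P(t)
        I = pernode_I(t)
        # divergence surfaces as non-finite state at the next record point;
        # overflow on the way there is expected, not worth a warning
        with np.errstate(over="ignore", invalid="ignore"):
            dv = (P - v * v) * v + jvw * w + I
            dw = (P - w * w) * w + jwv * v
            if use_J:
                dv += g * (J @ v)
                dw += gp * (J @ w)
        return dv, dw

    if initial is None:
        v, w = initial_state(n, config.seed, config.init_noise_amplitude)
    else:
        v = np.array(initial[0], dtype=float).copy()
        w = np.array(initial[1], dtype=float).copy()
        if v.shape != (n,) or w.shape != (n,):
            raise ValueError("initial state must have shape (n,)")

    dt = config.dt
    n_steps = int(round(config.duration / dt))
    stride = config.record_stride
    rec_steps = list(range(0, n_steps + 1, stride))
    if rec_steps[-1] != n_steps:
        rec_steps.append(n_steps)

    T = len(rec_steps)
    times = np.array([k * dt for k in rec_steps])
    V = np.empty((n, T))
    W = np.empty((n, T))
    Prec = np.empty((n, T))
    Irec = np.empty((n, T))

    rec_set = {k: idx for idx, k in enumerate(rec_steps)}
    rk4 = config.method == "rk4"

    for k in range(n_steps + 1):
        if k in rec_set:
            idx = rec_set[k]
            t = k * dt
            V[:, idx] = v
            W[:, idx] = w
            Prec[:, idx] = pernode_P(t)
            Irec[:, idx] = pernode_I(t)
            if not (np.all(np.isfinite(v)) and np.all(np.isfinite(w))):
                raise IntegrationError(
                    f"non-finite state at t={t:.6g}; "
                    f"reduce dt (currently {dt:.3g}) or check parameters"
                )
        if k == n_steps:
            break
        t = k * dt
        if rk4:
            k1v, k1w = rhs(t, v, w)
            k2v, k2w = rhs(t + dt / 2, v + dt / 2 * k1v, w + dt / 2 * k1w)
            k3v, k3w = rhs(t + dt / 2, v + dt / 2 * k2v, w + dt / 2 * k2w)
            k4v, k4w = rhs(t + dt, v + dt * k3v, w + dt * k3w)
            v = v + dt / 6 * (k1v + 2 * k2v + 2 * k3v + k4v)
            w = w + dt / 6 * (k1w + 2 * k2w + 2 * k3w + k4w)
        else:
            dv, dw = rhs(t, v, w)
            v = v + dt * dv
            w = w + dt * dw

    return Trajectory(times=times, v=V, w=W, pump=Prec, bias=Irec)


def simulate_with_schedules(
    params: NeuronParams,
    coupling: NetworkCoupling,
    config: SimulationConfig,
    pump_schedule: Schedule,
    bias_schedule: Schedule,
    initial: tuple[np.ndarray, np.ndarray] | None = None,
) -> Trajectory:
    """``simulate`` with explicit time-dependent pump and bias."""
    return simulate(
        params,
        coupling,
        config,
        initial=initial,
        pump_schedule=pump_schedule,
        bias_schedule=bias_schedule,
    )
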