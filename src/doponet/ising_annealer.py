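"""Pump-ramp spiking anneal for Ising instances, with an exact oracle.

The heuristic: encode the instance on the v-DOPOs (gamma = -J_k,
gamma' = 0, I_ext = 0) and ramp the node-independent pump P0(t) linearly
from below the spiking threshold to beyond the SNLC edge sqrt(8)*omega0.
While the network spikes, neurons with high local energy E_loc,i see an
effectively raised pump (P'_i = P0 - J_k E_loc,i / 2), keep firing, and so
keep flipping their spins; energetically stable neurons freeze first.  At
the end of the ramp the dynamics freeze everywhere and sign(v) is read out
as the spin configuration.  The best energy seen anywhere along the trace
is the solver output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binomtest

from .dopo_core import SimulationConfig, simulate
from .network_builders import IsingInstance, build_ising_network
from .observables import (
    EnergyTrace,
    detect_spikes,
    ising_energy,
    local_energy,
    renormalized_pump_ising,
)
from .reduced_dynamics import to_polar
from .schedules import linear_ramp

__all__ = [
    "AnnealSchedule",
    "AnnealResult",
    "BatchResult",
    "OracleResult",
    "run_anneal",
    "run_trials",
    "brute_force_ground_state",
]


@dataclass
class AnnealSchedule:
    """Linear pump ramp in dimensionless units.

    Defaults start below the oscillation threshold (P~ = -0.5, only noise)
    and end beyond the spiking-region edge sqrt(8) ~ 2.83 (P~ = 3.2), so
    the run ends in a frozen, readable state.
    """

    p_start: float = -0.5
    p_end: float = 3.2
    duration: float = 500.0
    j_k: float = 0.25
    shape: str = "linear"

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if self.shape != "linear":
            raise ValueError("only linear ramps are supported")


@dataclass
class AnnealResult:
    times: np.ndarray
    e_ising: np.ndarray
    best_energy: float
    best_sigma: np.ndarray
    final_sigma: np.ndarray
    final_e_loc: np.ndarray
    firing_counts: np.ndarray
    seed: int
    energy_trace: EnergyTrace | None = None
    diverged: bool = False


@dataclass
class BatchResult:
    trials: list
    best_energy: float
    best_sigma: np.ndarray
    reference_energy: float | None = None
    success_count: int | None = None
    success_probability: float | None = None
    success_ci95: tuple | None = None


@dataclass
class OracleResult:
    min_energy: float
    sigma: np.ndarray
    degeneracy: int  # number of minimizers, counted up to global spin flip


def run_anneal(
    instance: IsingInstance,
    schedule: AnnealSchedule,
    config: SimulationConfig | None = None,
    keep_trace: bool = False,
) -> AnnealResult:
    """One seeded annealing trial."""
    if config is None:
        config = SimulationConfig(
            dt=1e-2, duration=schedule.duration, record_stride=10
        )
    coupling, params = build_ising_network(instance, schedule.j_k)
    omega0 = params.omega0
    pump = linear_ramp(
        schedule.p_start * omega0,
        schedule.p_end * omega0,
        0.0,
        schedule.duration,
    )
    from .dopo_core import IntegrationError

    try:
        traj = simulate(params, coupling, config, pump_schedule=pump)
    except IntegrationError:
        nan = np.full(instance.n, np.nan)
        return AnnealResult(
            times=np.empty(0),
            e_ising=np.empty(0),
            best_energy=np.inf,
            best_sigma=nan,
            final_sigma=nan,
            final_e_loc=nan,
            firing_counts=np.zeros(instance.n, dtype=int),
            seed=config.seed,
            diverged=True,
        )

    sigma = np.where(traj.v >= 0, 1, -1)  # (n, T)
    Js = instance.J @ sigma
    e_loc = -sigma * Js
    e_ising = 0.5 * e_loc.sum(axis=0)

    best_idx = int(np.argmin(e_ising))
    spikes = detect_spikes(to_polar(traj))
    counts = spikes.counts

    p0 = traj.pump[0] if traj.pump is not None else None
    trace = None
    if keep_trace:
        trace = EnergyTrace(
            times=traj.times,
            sigma=sigma,
            e_ising=e_ising,
            e_loc=e_loc,
            firing_counts=counts,
            pump_renormalized=(
                None
                if p0 is None
                else renormalized_pump_ising(p0[None, :], schedule.j_k, e_loc)
            ),
        )
    return AnnealResult(
        times=traj.times,
        e_ising=e_ising,
        best_energy=float(e_ising[best_idx]),
        best_sigma=sigma[:, best_idx].copy(),
        final_sigma=sigma[:, -1].copy(),
        final_e_loc=e_loc[:, -1].copy(),
        firing_counts=counts,
        seed=config.seed,
        energy_trace=trace,
    )


def run_trials(
    instance: IsingInstance,
    schedule: AnnealSchedule,
    n_trials: int,
    base_seed: int = 0,
    reference_energy: float | None = None,
    config: SimulationConfig | None = None,
) -> BatchResult:
    """Independent seeded trials (seed = base_seed + trial index) with
    success statistics against a reference energy, if one is supplied."""
    if n_trials < 1:
        raise ValueError("need n_trials >= 1")
    if config is None:
        config = SimulationConfig(
            dt=1e-2, duration=schedule.duration, record_stride=10
        )
    trials = []
    for k in range(n_trials):
        cfg = SimulationConfig(
            dt=config.dt,
            duration=config.duration,
            method=config.method,
            record_stride=config.record_stride,
            seed=base_seed + k,
            init_noise_amplitude=config.init_noise_amplitude,
        )
        trials.append(run_anneal(instance, schedule, cfg))

    best = min(trials, key=lambda t: t.best_energy)
    result = BatchResult(
        trials=trials, best_energy=best.best_energy, best_sigma=best.best_sigma
    )
    if reference_energy is not None:
        succ = sum(t.best_energy <= reference_energy + 1e-9 for t in trials)
        ci = binomtest(succ, n_trials).proportion_ci(confidence_level=0.95)
        result.reference_energy = reference_energy
        result.success_count = succ
        result.success_probability = succ / n_trials
        result.success_ci95 = (float(ci.low), float(ci.high))
    return result


def brute_force_ground_state(
    instance: IsingInstance, max_n: int = 24, chunk: int = 1 << 14
) -> OracleResult:
    """Exact minimum by exhaustive enumeration over 2^(n-1) configurations
    (spin n fixed to +1; global flip symmetry halves the space)."""
    n = instance.n
    if n > max_n:
        raise ValueError(f"enumeration limited to n <= {max_n}, got {n}")
    J = instance.J
    total = 1 << (n - 1)
    best_e = np.inf
    best_cfg = None
    degeneracy = 0
    bits = np.arange(n - 1)
    for start in range(0, total, chunk):
        codes = np.arange(start, min(start + chunk, total), dtype=np.int64)
        S = np.ones((len(codes), n))
        S[:, :-1] = 1.0 - 2.0 * ((codes[:, None] >> bits[None, :]) & 1)
        E = -0.5 * np.einsum("ki,ij,kj->k", S, J, S)
        E = np.round(E, 9)  # exact for integer weights, stable ties otherwise
        cmin = E.min()
        if cmin < best_e - 1e-12:
            best_e = cmin
            best_cfg = S[int(np.argmin(E))].copy()
            degeneracy = int(np.sum(np.abs(E - cmin) < 1e-9))
        elif abs(cmin - best_e) < 1e-9:
            degeneracy += int(np.sum(np.abs(E - best_e) < 1e-9))
    sigma = best_cfg.astype(int)
    assert abs(ising_energy(J, sigma) - best_e) < 1e-6
    return OracleResult(min_energy=float(best_e), sigma=sigma, degeneracy=degeneracy)
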