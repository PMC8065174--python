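"""Measured quantities: spikes, synchronization, Ising/local energies.

Conventions
-----------
* A spike is one full 2*pi advance of the unwrapped phase theta_i (the
  sin 4 theta potential has four-fold symmetry, so quarter-turn detectors
  are ambiguous; the full revolution is not).  The detector tag travels
  with every SpikeTrain.
* Firing rates are reported as angular frequencies (2 pi * revolutions per
  unit time) so they compare directly with the dimensionless omega~.
* Ising readout: sigma_i = sign(v_i), with sign(0) -> +1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .dopo_core import Trajectory
from .reduced_dynamics import PolarTrajectory, to_polar

__all__ = [
    "SpikeTrain",
    "SyncReport",
    "EnergyTrace",
    "FiringEnergyCorrelation",
    "order_parameter",
    "detect_spikes",
    "phase_increment",
    "ising_energy",
    "local_energy",
    "spin_readout",
    "renormalized_pump",
    "renormalized_pump_ising",
    "sync_report",
    "firing_vs_local_energy",
]


@dataclass
class SpikeTrain:
    spike_times: list  # per neuron, strictly increasing 1-D arrays
    definition: str  # "winding" or "amplitude-peak"
    rates: np.ndarray  # angular frequency per neuron

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(s) for s in self.spike_times])

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (i, t)
            for i, times in enumerate(self.spike_times)
            for t in times
        ]
        return pd.DataFrame(rows, columns=["neuron", "spike_time"])


@dataclass
class SyncReport:
    times: np.ndarray
    r_global: np.ndarray  # (T,)
    r_cluster: dict  # label -> (T,)
    delta_theta: np.ndarray  # (n, n_windows)
    window_times: np.ndarray
    r_global_mean: float  # time average after transient
    n: int

    def to_dataframe(self) -> pd.DataFrame:
        d = {"time": self.times, "r_global": self.r_global}
        for label, trace in self.r_cluster.items():
            d[f"r_{label}"] = trace
        return pd.DataFrame(d)


@dataclass
class EnergyTrace:
    times: np.ndarray
    sigma: np.ndarray  # (n, T) in {-1, +1}
    e_ising: np.ndarray  # (T,)
    e_loc: np.ndarray  # (n, T)
    firing_counts: np.ndarray  # (n,)
    pump_renormalized: np.ndarray | None = None  # (n, T): P0(t) - J_k E_loc / 2


@dataclass
class FiringEnergyCorrelation:
    table: pd.DataFrame  # neuron, firing_count, e_loc
    pearson: float
    spearman: float
    undefined: bool


def order_parameter(theta, membership=None):
    """Kuramoto order parameter r = |mean_j exp(i theta_j)|.

    ``theta`` may be (n,) for a scalar r or (n, T) for an r(t) trace;
    ``membership`` restricts the average to the given neuron indices.
    """
    th = np.asarray(theta, dtype=float)
    if th.ndim == 1:
        th = th[:, None]
        squeeze = True
    else:
        squeeze = False
    if membership is not None:
        idx = np.asarray(membership)
        if idx.size == 0:
            raise ValueError("empty membership")
        th = th[idx]
    r = np.abs(np.mean(np.exp(1j * th), axis=0))
    return float(r[0]) if squeeze else r


def _winding_spikes(times: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Times of each full 2*pi advance of one unwrapped phase trace."""
    adv = theta - theta[0]
    direction = 1.0 if adv[-1] >= 0 else -1.0
    s = direction * adv
    n_rev = int(np.floor(np.max(s) / (2 * np.pi)))
    if n_rev < 1:
        return np.empty(0)
    out = np.empty(n_rev)
    k = 0
    level = 2 * np.pi
    for idx in range(1, len(s)):
        while s[idx] >= level and k < n_rev:
            # linear interpolation of the crossing time
            f = (level - s[idx - 1]) / (s[idx] - s[idx - 1])
            out[k] = times[idx - 1] + f * (times[idx] - times[idx - 1])
            k += 1
            level += 2 * np.pi
        if k >= n_rev:
            break
    return out[:k]


def detect_spikes(
    data: PolarTrajectory | Trajectory,
    definition: str = "winding",
    peak_threshold: float = 0.5,
    min_R: float = 0.05,
) -> SpikeTrain:
    """Locate spikes and compute per-neuron firing rates.

    ``winding``: one spike per full 2*pi advance of unwrapped theta,
    timestamped by linear interpolation of the crossing.  When the
    amplitude channel is present, crossings with R < ``min_R`` are
    discarded: a decaying subthreshold focus still winds in phase, but a
    spiral at noise amplitude is not a spike.  (Steady spiking has
    R ~ sqrt(2) P, orders of magnitude above the default gate.)
    ``amplitude-peak``: local maxima of |v| above ``peak_threshold``.
    Rate = 2*pi*(count - 1)/(t_last - t_first) for count >= 2, else 0.
    """
    if definition == "winding":
        polar = data if isinstance(data, PolarTrajectory) else to_polar(data)
        trains = []
        for i in range(polar.n_neurons):
            st = _winding_spikes(polar.times, polar.theta[i])
            if polar.R is not None and min_R > 0 and len(st):
                R_at = np.interp(st, polar.times, polar.R[i])
                st = st[R_at >= min_R]
            trains.append(st)
    elif definition == "amplitude-peak":
        traj = data
        if isinstance(data, PolarTrajectory):
            from .reduced_dynamics import from_polar

            traj = from_polar(data)
        trains = []
        for i in range(traj.n_neurons):
            peaks, _ = signal.find_peaks(np.abs(traj.v[i]), height=peak_threshold)
            trains.append(traj.times[peaks])
    else:
        raise ValueError(f"unknown spike definition {definition!r}")

    rates = np.zeros(len(trains))
    for i, st in enumerate(trains):
        if len(st) >= 2:
            rates[i] = 2 * np.pi * (len(st) - 1) / (st[-1] - st[0])
    return SpikeTrain(spike_times=trains, definition=definition, rates=rates)


def phase_increment(polar: PolarTrajectory, window: float) -> tuple[np.ndarray, np.ndarray]:
    """Phase change per consecutive window of length ``window``.

    Returns (window_end_times, delta_theta) with delta_theta of shape
    (n, n_windows).  Near-zero stretches mark class-I stalling at
    unstable stationary points.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    t0, t1 = polar.times[0], polar.times[-1]
    if window > t1 - t0:
        raise ValueError("window longer than the trace")
    edges = np.arange(t0, t1 + 1e-12, window)
    th_at = np.vstack(
        [np.interp(edges, polar.times, polar.theta[i]) for i in range(polar.n_neurons)]
    )
    return edges[1:], np.diff(th_at, axis=1)


def _validate_spins(sigma: np.ndarray) -> np.ndarray:
    s = np.asarray(sigma)
    if not np.all(np.isin(s, (-1, 1))):
        raise ValueError("spins must be in {-1, +1}")
    return s.astype(float)


def ising_energy(J: np.ndarray, sigma) -> float:
    """E_Ising = -sum_{i<j} J_ij sigma_i sigma_j (J symmetric, zero diag)."""
    s = _validate_spins(sigma)
    J = np.asarray(J, dtype=float)
    return float(-0.5 * s @ (J @ s))


def local_energy(J: np.ndarray, sigma) -> np.ndarray:
    """E_loc,i = -sum_j J_ij sigma_i sigma_j;  E_Ising = (1/2) sum_i E_loc,i."""
    s = _validate_spins(sigma)
    J = np.asarray(J, dtype=float)
    return -s * (J @ s)


def spin_readout(traj: Trajectory, time: float | None = None) -> np.ndarray:
    """sigma_i = sign(v_i(t)) at the requested time (default: end of run);
    exact zeros map to +1."""
    if time is None:
        idx = len(traj.times) - 1
    else:
        if time < traj.times[0] or time > traj.times[-1]:
            raise ValueError("readout time outside the trace")
        idx = int(np.argmin(np.abs(traj.times - time)))
    v = traj.v[:, idx]
    return np.where(v >= 0, 1, -1).astype(int)


def renormalized_pump(P, r, N: int, j_k: float):
    """Mean-field effective pump of a synchronized cluster:
    P' = P + r (N - 1) J_k  (eps_ij ~ 1 approximation)."""
    return np.asarray(P) + np.asarray(r) * (N - 1) * j_k


def renormalized_pump_ising(P0, j_k: float, e_loc):
    """Effective pump in the Ising encoding: P' = P0 - (1/2) J_k E_loc,i.
    (The mean-field eps_ij ~ 1 route gives coefficient 1 instead of 1/2;
    see the methods note.  This is the form used for diagnostics.)"""
    return np.asarray(P0) - 0.5 * j_k * np.asarray(e_loc)


def sync_report(
    polar: PolarTrajectory,
    labels=None,
    window: float | None = None,
    transient_fraction: float = 0.25,
) -> SyncReport:
    """Order-parameter traces (global and per cluster) and windowed phase
    increments.  ``window`` defaults to 4 recorded samples, the analogue of
    four cavity circulations."""
    th = polar.theta
    n = polar.n_neurons
    r_global = order_parameter(th)
    r_cluster: dict = {}
    if labels is not None:
        labels = np.asarray(labels)
        for lab in np.unique(labels):
            r_cluster[str(lab)] = order_parameter(th, np.where(labels == lab)[0])
    if window is None:
        dt_rec = np.median(np.diff(polar.times))
        window = 4.0 * float(dt_rec)
    wtimes, dth = phase_increment(polar, window)
    tcut = polar.times[0] + transient_fraction * (polar.times[-1] - polar.times[0])
    return SyncReport(
        times=polar.times,
        r_global=r_global,
        r_cluster=r_cluster,
        delta_theta=dth,
        window_times=wtimes,
        r_global_mean=float(np.mean(r_global[polar.times >= tcut])),
        n=n,
    )


def firing_vs_local_energy(spikes: SpikeTrain, e_loc: np.ndarray) -> FiringEnergyCorrelation:
    """Correlation between per-neuron total firing count and final local
    energy (the self-tuning signature: energetically unstable neurons fire
    more under strong coupling)."""
    counts = spikes.counts.astype(float)
    e_loc = np.asarray(e_loc, dtype=float)
    if counts.shape != e_loc.shape:
        raise ValueError("firing counts and local energies misaligned")
    table = pd.DataFrame(
        {"neuron": np.arange(len(counts)), "firing_count": counts, "e_loc": e_loc}
    )
    if np.std(counts) == 0 or np.std(e_loc) == 0:
        return FiringEnergyCorrelation(
            table=table, pearson=float("nan"), spearman=float("nan"), undefined=True
        )
    pear = float(stats.pearsonr(counts, e_loc).statistic)
    spear = float(stats.spearmanr(counts, e_loc).statistic)
    return FiringEnergyCorrelation(
        table=table, pearson=pear, spearman=spear, undefined=False
    )
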