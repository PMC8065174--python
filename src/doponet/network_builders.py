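"""Builders for the two network families used throughout the package.

* Clustered Kuramoto-style ensembles: all-to-all clusters of DOPO neurons
  (coupling encoded on both the v- and w-DOPOs, gamma = gamma' = J_k) with
  sparse random inter-cluster links and a per-cluster pump assignment that
  shapes the intrinsic firing-rate distribution omega(P_i).
* Ising-encoded networks: a symmetric spin-glass weight matrix wired only
  between v-DOPOs with gamma = -J_k, gamma' = 0 and zero bias, so that the
  binary sign of v represents an Ising spin.

Plus a seeded Erdos-Renyi generator of random +/-1 (or real-weight) Ising
instances and a plain-text edge-list format for them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dopo_core import NetworkCoupling, NeuronParams
from .reduced_dynamics import omega_closed_form

__all__ = [
    "ClusteredNetworkSpec",
    "IsingInstance",
    "build_clustered_network",
    "assign_pump_spread",
    "build_ising_network",
    "generate_random_instance",
    "write_instance",
    "read_instance",
]

P_TILDE_MAX = float(np.sqrt(8.0))


@dataclass
class ClusteredNetworkSpec:
    """All-to-all clusters with sparse inter-cluster links.

    ``pump_centers`` lists the per-cluster dimensionless pump P~ in the
    order cluster A, B, C, ...; since omega(P) is decreasing, ascending
    centers give clusters in descending order of intrinsic firing rate.
    Each cluster's neurons are spread evenly over
    [center - half_spread, center + half_spread].
    """

    n_clusters: int = 4
    cluster_size: int = 15
    j_k: float = 0.025
    pump_centers: tuple = (0.5, 1.0, 1.5, 2.0)
    pump_half_spread: float = 0.15
    inter_edges_per_pair: int = 2
    inter_strength_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.cluster_size < 1:
            raise ValueError("need >= 1 cluster of >= 1 neuron")
        if len(self.pump_centers) != self.n_clusters:
            raise ValueError("one pump center per cluster required")

    @property
    def n_neurons(self) -> int:
        return self.n_clusters * self.cluster_size

    @property
    def labels(self) -> np.ndarray:
        """Cluster label per neuron: 'A', 'B', ... contiguous blocks."""
        letters = [chr(ord("A") + c) for c in range(self.n_clusters)]
        return np.repeat(letters, self.cluster_size)


def assign_pump_spread(
    n_neurons: int,
    centers,
    half_spread: float = 0.0,
    labels=None,
) -> np.ndarray:
    """Deterministic per-neuron dimensionless pumps P~_i, grouped by cluster.

    Within each cluster the pumps are evenly spaced across
    [center - half_spread, center + half_spread]; every value must lie in
    the spiking domain (0, sqrt(8)).
    """
    centers = np.atleast_1d(np.asarray(centers, dtype=float))
    if labels is None:
        if n_neurons % len(centers):
            raise ValueError("n_neurons must divide evenly over the clusters")
        labels = np.repeat(np.arange(len(centers)), n_neurons // len(centers))
    labels = np.asarray(labels)
    if len(labels) != n_neurons:
        raise ValueError("labels must have one entry per neuron")

    p = np.empty(n_neurons)
    for ci, lab in enumerate(dict.fromkeys(labels.tolist())):
        idx = np.where(labels == lab)[0]
        m = len(idx)
        c = centers[ci]
        if m == 1 or half_spread == 0:
            vals = np.full(m, c)
        else:
            vals = np.linspace(c - half_spread, c + half_spread, m)
        p[idx] = vals
    if np.any(p <= 0) or np.any(p >= P_TILDE_MAX):
        raise ValueError(
            f"pump values must lie inside the spiking domain (0, {P_TILDE_MAX:.4f})"
        )
    return p


def build_clustered_network(
    spec: ClusteredNetworkSpec,
) -> tuple[NetworkCoupling, NeuronParams]:
    """Coupling matrix + per-neuron params for the clustered ensemble.

    Intra-cluster entries are 1 (all-to-all), inter-cluster pairs get
    ``inter_edges_per_pair`` random edges of relative strength
    ``inter_strength_factor``; the overall strength enters through
    gamma = gamma' = J_k.
    """
    n = spec.n_neurons
    J = np.zeros((n, n))
    blocks = [
        np.arange(c * spec.cluster_size, (c + 1) * spec.cluster_size)
        for c in range(spec.n_clusters)
    ]
    for idx in blocks:
        J[np.ix_(idx, idx)] = 1.0
    np.fill_diagonal(J, 0.0)

    rng = np.random.default_rng([spec.seed, 17])
    for a, b_ in itertools.combinations(range(spec.n_clusters), 2):
        for _ in range(spec.inter_edges_per_pair):
            i = rng.choice(blocks[a])
            j = rng.choice(blocks[b_])
            J[i, j] = J[j, i] = spec.inter_strength_factor

    coupling = NetworkCoupling(n=n, J=J, gamma=spec.j_k, gamma_prime=spec.j_k)
    p_tilde = assign_pump_spread(
        n, spec.pump_centers, spec.pump_half_spread, labels=spec.labels
    )
    params = NeuronParams.from_tilde(p_tilde, i_ext_tilde=0.0)
    return coupling, params


@dataclass
class IsingInstance:
    """Symmetric spin-glass weight matrix with zero diagonal."""

    n: int
    J: np.ndarray
    density: float | None = None  # realized edge density
    seed: int | None = None
    known_energy: float | None = None

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=float)
        if self.J.shape != (self.n, self.n):
            raise ValueError(f"J must be {self.n}x{self.n}")
        if not np.allclose(self.J, self.J.T):
            raise ValueError("J must be symmetric")
        if np.any(np.diag(self.J) != 0):
            raise ValueError("J must have zero diagonal")
        realized = self.edge_count / (self.n * (self.n - 1) / 2)
        if self.density is None:
            self.density = realized
        elif abs(self.density - realized) > 1e-12:
            raise ValueError("density metadata does not match realized density")

    @property
    def edge_count(self) -> int:
        iu = np.triu_indices(self.n, k=1)
        return int(np.count_nonzero(self.J[iu]))


def generate_random_instance(
    n: int,
    density: float,
    weight_scheme: str = "pm1",
    seed: int = 0,
) -> IsingInstance:
    """Seeded Erdos-Renyi instance: each of the C(n,2) edges present with
    probability ``density``; weights +/-1 equiprobable (``pm1``) or
    uniform on [-1, 1) (``uniform``)."""
    if n < 2:
        raise ValueError("need n >= 2 spins")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng([seed, n])
    J = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    present = rng.random(len(iu[0])) < density
    if weight_scheme == "pm1":
        weights = rng.choice([-1.0, 1.0], size=len(iu[0]))
    elif weight_scheme == "uniform":
        weights = rng.uniform(-1.0, 1.0, size=len(iu[0]))
    else:
        raise ValueError(f"unknown weight scheme {weight_scheme!r}")
    vals = np.where(present, weights, 0.0)
    J[iu] = vals
    J = J + J.T
    inst = IsingInstance(n=n, J=J, seed=seed)
    if inst.edge_count == 0:
        raise ValueError("requested density produced an empty graph")
    return inst


def build_ising_network(
    instance: IsingInstance, j_k: float
) -> tuple[NetworkCoupling, NeuronParams]:
    """Ising encoding: spin-spin weights only between v-DOPOs and zero
    external bias.

    Sign convention: with E_Ising = -sum_{i<j} J_ij sigma_i sigma_j and
    sigma_i = sign(v_i), minimizing E_Ising requires gamma = +J_k here:
    the coupling then renormalizes the pump as P'_i = P0 - J_k E_loc,i / 2,
    so energetically stable neurons (low E_loc) freeze first and unstable
    ones keep spiking and flipping.  (gamma = -J_k anneals on -J, i.e.
    maximizes E_Ising for the same weights.)
    """
    coupling = NetworkCoupling(
        n=instance.n, J=instance.J, gamma=j_k, gamma_prime=0.0
    )
    params = NeuronParams.from_tilde(np.zeros(instance.n), i_ext_tilde=0.0)
    return coupling, params


# ---------------------------------------------------------------------------
# Edge-list text format: header "n m", then m lines "i j w" (1-based),
# symmetric pairs stored once; '#' lines are comments.


def write_instance(instance: IsingInstance, path) -> None:
    path = Path(path)
    iu = np.triu_indices(instance.n, k=1)
    rows = [
        (i + 1, j + 1, instance.J[i, j])
        for i, j in zip(*iu)
        if instance.J[i, j] != 0
    ]
    with path.open("w") as fh:
        fh.write(f"{instance.n} {len(rows)}\n")
        for i, j, w in rows:
            fh.write(f"{i} {j} {w:.17g}\n")


def read_instance(path) -> IsingInstance:
    path = Path(path)
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise ValueError(f"empty instance file {path}")
    n, m = (int(x) for x in lines[0].split())
    J = np.zeros((n, n))
    if len(lines) - 1 != m:
        raise ValueError(f"header declares {m} edges, file has {len(lines) - 1}")
    for ln in lines[1:]:
        si, sj, sw = ln.split()
        i, j = int(si) - 1, int(sj) - 1
        if not (0 <= i < n and 0 <= j < n) or i == j:
            raise ValueError(f"bad edge '{ln}'")
        w = float(sw)
        J[i, j] = J[j, i] = w
    return IsingInstance(n=n, J=J)
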