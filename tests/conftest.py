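"""Shared fixtures.

The two expensive simulation campaigns (the 4x15-neuron clustered
synchronization sweep and the n=16 Ising annealing batches) are
session-scoped so the acceptance tests and the module tests share one
run of each.
"""

from __future__ import annotations

import numpy as np
import pytest

import doponet as dn

CLUSTER_JK = (0.0, 0.025, 0.05, 0.075)
ANNEAL_JK = (0.083, 0.167, 0.25)


@pytest.fixture(scope="session")
def cluster_runs():
    """Clustered 4x15 ensemble simulated at each coupling strength.

    Returns {j_k: dict} with the network spec, steady-state polar
    trajectory (transient discarded), spike trains and sync report.
    """
    out = {}
    for j_k in CLUSTER_JK:
        spec = dn.ClusteredNetworkSpec(j_k=j_k, seed=0)
        coupling, params = dn.build_clustered_network(spec)
        config = dn.SimulationConfig(
            dt=1e-2, duration=400.0, record_stride=10, seed=11
        )
        traj = dn.simulate(params, coupling, config)
        polar = dn.to_polar(traj.window(100.0))
        spikes = dn.detect_spikes(polar)
        report = dn.sync_report(polar, labels=spec.labels)
        out[j_k] = {
            "spec": spec,
            "polar": polar,
            "spikes": spikes,
            "report": report,
        }
    return out


@pytest.fixture(scope="session")
def ising_instance():
    return dn.generate_random_instance(16, 0.5, "pm1", seed=0)


@pytest.fixture(scope="session")
def ising_oracle(ising_instance):
    return dn.brute_force_ground_state(ising_instance)


@pytest.fixture(scope="session")
def anneal_batches(ising_instance, ising_oracle):
    """20 seeded annealing trials per coupling strength on one instance."""
    out = {}
    for j_k in ANNEAL_JK:
        schedule = dn.AnnealSchedule(j_k=j_k)
        out[j_k] = dn.run_trials(
            ising_instance,
            schedule,
            n_trials=20,
            base_seed=1000,
            reference_energy=ising_oracle.min_energy,
        )
    return out
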