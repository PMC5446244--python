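"""Shared fixtures: reference networks and the expensive trained artifacts.

Training runs and scans are session-scoped so the structure, robustness and
speed-control tests share one tutored network instead of retraining.
"""

from __future__ import annotations

import numpy as np
import pytest

from striseq import analysis, core_rate, plasticity, spiking


WIRED10 = dict(n_units=10, tau_y=20.0, beta=0.2, lam=20.0)


@pytest.fixture(scope="session")
def wired10_params():
    return core_rate.RateNetworkParams(**WIRED10)


@pytest.fixture(scope="session")
def wired10_weights():
    return core_rate.build_sequence_weights(10, eta=0.1, cyclic=True)


@pytest.fixture(scope="session")
def wired10_scan(wired10_params, wired10_weights):
    """Mean switch times over 7 effective-drive levels spanning [0.3, 0.9]."""
    levels = np.linspace(0.3, 0.9, 7)
    return core_rate.scan_switch_times(wired10_params, wired10_weights, levels, eta=0.1)


@pytest.fixture(scope="session")
def training_params():
    return core_rate.RateNetworkParams(n_units=15, tau_y=20.0, beta=0.2, lam=20.0)


@pytest.fixture(scope="session")
def pulse_training(training_params):
    """A 15-unit network tutored on a seeded random cyclic order (20 pulse cycles)."""
    rng = np.random.default_rng(0)
    order = [int(u) for u in rng.permutation(15)]
    protocol = plasticity.make_training_protocol(
        "pulses", 15, cycle_length=25 * training_params.tau_y, cycles=20, seed=0, order=order
    )
    W0 = plasticity.random_weights(15, seed=100)
    run = plasticity.train_network(W0, protocol, plasticity.PlasticityParams(), training_params)
    return {"order": order, "W0": W0, "run": run}


@pytest.fixture(scope="session")
def spiking_trained():
    """Clustered EIF network after 20 noisy cycles of sin^8 tutoring with STDP."""
    params = spiking.SpikingParams()
    net = spiking.build_clustered_network(n_clusters=8, cluster_size=100, p_connect=0.2, seed=1)
    drive = spiking.make_sin8_input(spiking.Sin8InputParams(seed=7), 8, net.membership)
    result = spiking.simulate_spiking(
        net, drive, duration=20 * 800.0, params=params, stdp=spiking.STDPParams()
    )
    taught = analysis.sequence_from_spikes(
        result.spike_times, result.spike_neurons, net.membership, bin_width=20.0
    )
    return {"params": params, "network": net, "result": result, "taught": taught}


def rotation_equal(a: list[int], b: list[int]) -> bool:
    """True if b is a cyclic rotation of a."""
    if len(a) != len(b) or not a or a[0] not in b:
        return False
    i = b.index(a[0])
    return b[i:] + b[:i] == a
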