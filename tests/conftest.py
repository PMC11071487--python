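"""Shared fixtures: toy morphologies and synapse maps, generated in-process."""

import numpy as np
import pytest

import dendrotopo as dt


@pytest.fixture(scope="session")
def toy_dn():
    """Seed-1 toy DN morphology with SIZ annotation."""
    return dt.make_toy_dn(dt.ToyDNSpec(seed=1))


@pytest.fixture(scope="session")
def passive_params():
    return dt.PassiveParams(cm=0.8, g_leak=3.17e-4, ra=50.0, e_rev=-61.15)


@pytest.fixture(scope="session")
def clustered_map(toy_dn):
    spec = dt.SynapsePlacementSpec(seed=0, n_neurons=10,
                                   synapses_per_neuron=15, mode="clustered",
                                   sigma_cluster=8.0)
    placed = dt.place_synapses(toy_dn, spec)
    return dt.map_to_skeleton(placed.records, toy_dn)


@pytest.fixture(scope="session")
def random_map(toy_dn):
    spec = dt.SynapsePlacementSpec(seed=0, n_neurons=10,
                                   synapses_per_neuron=15, mode="random")
    placed = dt.place_synapses(toy_dn, spec)
    return dt.map_to_skeleton(placed.records, toy_dn)


@pytest.fixture(scope="session")
def toy_model(toy_dn, passive_params, clustered_map):
    return dt.build_model(toy_dn, passive_params, clustered_map)


def straight_cable(n_nodes=201, length=400.0, radius=0.5, label="dendrite"):
    """Unbranched cable along +x with given total length."""
    nodes = [dt.SkeletonNode(1, -1, np.zeros(3), radius, label)]
    for i in range(2, n_nodes + 1):
        x = length * (i - 1) / (n_nodes - 1)
        nodes.append(dt.SkeletonNode(i, i - 1, np.array([x, 0.0, 0.0]),
                                     radius, label))
    return dt.Morphology(nodes)


@pytest.fixture(scope="session")
def uniform_cable():
    return straight_cable()
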