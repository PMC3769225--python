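"""Shared fixtures: synthetic structures and their networks/spectra."""

import numpy as np
import pytest

import allonet as al
from allonet.structure import BuildConfig, LigationState, build_network
from allonet.synthetic import ToyDimerConfig, toy_dimer, toy_monomer


@pytest.fixture(scope="session")
def dimer_model():
    """Deterministic C2-symmetric toy homodimer with two ligand instances."""
    return toy_dimer(ToyDimerConfig(seed=1))


@pytest.fixture(scope="session")
def monomer_model():
    return toy_monomer(ToyDimerConfig(seed=1))


@pytest.fixture(scope="session")
def config():
    return BuildConfig()


@pytest.fixture(scope="session")
def dimer_networks(dimer_model, config):
    sites = dimer_model.ligand_instances
    return {
        "apo": build_network(dimer_model, config, LigationState.apo()),
        "holo1A": build_network(dimer_model, config, LigationState.holo1(sites[0])),
        "holo1B": build_network(dimer_model, config, LigationState.holo1(sites[1])),
        "holo2": build_network(dimer_model, config, LigationState.holo2()),
    }


@pytest.fixture(scope="session")
def dimer_spectra(dimer_networks):
    return {
        name: al.eigenmodes(al.hessian(net))
        for name, net in dimer_networks.items()
    }


def random_connected_network(n_nodes=10, seed=0, k=1.0, cutoff=None):
    """Small random bead cloud guaranteed connected at its cutoff."""
    rng = np.random.default_rng(seed)
    for attempt in range(50):
        coords = rng.uniform(0, 8.0, size=(n_nodes, 3))
        from allonet.structure import StructureModel
        model = StructureModel(
            tuple(("A", i + 1, "GLY", coords[i]) for i in range(n_nodes)),
            (), f"random-{seed}-{attempt}",
        )
        try:
            return build_network(
                model, BuildConfig(spring_constant=k, cutoff=cutoff or 6.0),
                LigationState.apo(),
            )
        except ValueError:
            continue
    raise RuntimeError("no connected draw")
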