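"""Shared fixtures.  Expensive network simulations are session-scoped."""

import numpy as np
import pytest

import lowrank_snn as ls


@pytest.fixture(scope="session")
def params():
    return ls.BiophysicalParameters()


@pytest.fixture(scope="session")
def consts(params):
    return ls.derive_constants(params)


@pytest.fixture(scope="session")
def gamma_connectivity(params):
    """One full-size network at the gamma operating point (seed 42)."""
    return ls.assemble_connectivity(ls.ConnectivityConfig(), params.N_E,
                                    params.N_I, 42)


@pytest.fixture(scope="session")
def gamma_run(gamma_connectivity, params):
    """A 1.5 s unstimulated simulation at the gamma operating point."""
    return ls.run_simulation(gamma_connectivity, params,
                             ls.SimulationConfig(duration=1500.0), rng=43)


@pytest.fixture(scope="session")
def two_neuron():
    conn, p = ls.make_fixture("two_neuron")
    return conn, p
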