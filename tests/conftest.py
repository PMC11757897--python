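"""Shared fixtures.

The heavier artifacts (equilibrium sets, bifurcation sweeps) are
session-scoped so the enumeration and continuation runs are paid for once
and shared between the unit, property and acceptance tests.
"""

import numpy as np
import pytest

from hemonet.fixtures import FixtureSpec, build_extended_triangle, build_triangle
from hemonet.steady_state import compile_network
from hemonet.continuation import classify_flow_state, multistart_equilibria
from hemonet.experiments import beta_sweep


@pytest.fixture(scope="session")
def triangle_net():
    return build_triangle()


@pytest.fixture(scope="session")
def extended_net():
    return build_extended_triangle()


@pytest.fixture(scope="session")
def triangle_sys(triangle_net):
    return compile_network(triangle_net)


@pytest.fixture(scope="session")
def extended_sys(extended_net):
    return compile_network(extended_net)


@pytest.fixture(scope="session")
def triangle_equilibria(triangle_sys):
    eq = multistart_equilibria(triangle_sys, n_starts=200, seed=1)
    assert len(eq) == 3
    return eq


@pytest.fixture(scope="session")
def extended_equilibria(extended_sys):
    eq = multistart_equilibria(extended_sys, n_starts=600, seed=1)
    assert len(eq) == 9
    return eq


@pytest.fixture(scope="session")
def triangle_labels(triangle_equilibria):
    return classify_flow_state(triangle_equilibria)


@pytest.fixture(scope="session")
def extended_labels(extended_equilibria):
    return classify_flow_state(extended_equilibria)


@pytest.fixture(scope="session")
def triangle_beta_sweep(triangle_net, triangle_equilibria):
    return beta_sweep(triangle_net, (0.5, 1.5), seeds=triangle_equilibria, seed=1)


@pytest.fixture(scope="session")
def extended_beta_sweep(extended_net, extended_equilibria):
    return beta_sweep(extended_net, (0.2, 2.6), seeds=extended_equilibria, seed=1)
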