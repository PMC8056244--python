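"""Shared model fixtures: tiny analytically solvable systems."""

import pytest

from kinmod import Model
from kinmod.ratelaws import Constant, MassAction


@pytest.fixture
def decay_model():
    """dx/dt = -k x with k = 1: x(t) = x0 exp(-t)."""
    m = Model(parameters={"k": 1.0}, compounds=["x"])
    m.add_reaction("decay", MassAction("k", ("x",)), {"x": -1})
    return m


@pytest.fixture
def source_sink_model():
    """dS/dt = k0 - k1 S: steady state S = k0/k1, steady flux k0."""
    m = Model(parameters={"k0": 2.0, "k1": 4.0}, compounds=["S"])
    m.add_reaction("influx", Constant("k0"), {"S": 1})
    m.add_reaction("efflux", MassAction("k1", ("S",)), {"S": -1})
    return m


@pytest.fixture
def chain_model():
    """A -> B -> 0, mass action k1 = 1, k2 = 2 (closed-form cascade)."""
    m = Model(parameters={"k1": 1.0, "k2": 2.0}, compounds=["A", "B"])
    m.add_reaction("v1", MassAction("k1", ("A",)), {"A": -1, "B": 1})
    m.add_reaction("v2", MassAction("k2", ("B",)), {"B": -1})
    return m
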