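"""Shared fixtures: canonical nets and a seeded random-net generator used
by the property tests."""

from __future__ import annotations

import numpy as np
import pytest

from hpnsim import expressions as ex
from hpnsim import fixtures as fx
from hpnsim.model import HybridPetriNet, Place, Transition


@pytest.fixture
def calcium_net():
    """Single-channel calcium model: 2 discrete + 1 continuous place,
    2 stochastic + 2 continuous transitions."""
    return fx.make_single_channel_calcium()


@pytest.fixture
def immigration_death():
    return fx.make_immigration_death()


class StubStream:
    """Deterministic stand-in for RandomStream with preset uniforms."""

    def __init__(self, values):
        self.values = list(values)

    def uniform(self) -> float:
        return self.values.pop(0)

    def exponential(self, rate: float) -> float:
        return -np.log(self.uniform()) / rate


@pytest.fixture
def stub_stream():
    return StubStream


def random_net(seed: int, n_places: int = 4, n_transitions: int = 4,
               max_marking: int = 3) -> HybridPetriNet:
    """Small random discrete net with mass-action stochastic transitions.

    Structurally valid by construction; used as input for the enabledness,
    propensity and dependency-graph property tests.
    """
    rng = np.random.default_rng(seed)
    net = HybridPetriNet(f"random_{seed}")
    for i in range(n_places):
        net.add_place(Place(f"p{i}", "discrete",
                            int(rng.integers(0, max_marking + 1))))
    place_ids = list(net.places)
    for j in range(n_transitions):
        k = float(rng.uniform(0.5, 3.0))
        net.set_parameter(f"k{j}", k)
        net.add_transition(Transition(
            f"t{j}", "stochastic",
            ex.Call("MassAction", (ex.Ref(f"k{j}", "param"),))))
        n_in = int(rng.integers(1, 3))
        n_out = int(rng.integers(0, 3))
        inputs = rng.choice(place_ids, size=n_in, replace=False)
        for pid in inputs:
            kind = rng.choice(["standard", "standard", "read", "inhibitor"])
            net.add_arc(str(pid), f"t{j}", str(kind),
                        float(rng.integers(1, 3)))
        outputs = rng.choice(place_ids, size=n_out, replace=False) \
            if n_out else []
        for pid in outputs:
            net.add_arc(f"t{j}", str(pid), "standard",
                        float(rng.integers(1, 3)))
    return net


def all_markings(net: HybridPetriNet, upto: int = 3):
    """Exhaustive marking grid {0..upto}^|P| for brute-force oracles."""
    import itertools
    ids = list(net.places)
    for combo in itertools.product(range(upto + 1), repeat=len(ids)):
        yield dict(zip(ids, (float(c) for c in combo)))
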