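import numpy as np
import pytest

from senesim.network import (
    InputSignal,
    NetworkModel,
    ObservableDef,
    ReactionDef,
    SpeciesDef,
    build_reference_network,
)
from senesim.simulate import SimulationSettings


@pytest.fixture(scope="session")
def reference_model():
    return build_reference_network()


@pytest.fixture(scope="session")
def coarse_settings():
    """Coarser reporting grid for desk-scale tests (same solver tolerances)."""
    return SimulationSettings(interval_size=0.1)


@pytest.fixture(scope="session")
def reference_trajectory(reference_model, coarse_settings):
    from senesim.simulate import simulate_deterministic

    return simulate_deterministic(reference_model, settings=coarse_settings)


def linear_decay_model(rate=1.0, x0=1.0):
    """dx/dt = -rate * x."""
    return NetworkModel(
        [SpeciesDef("A", "A", x0, "IIS-mTOR")],
        [ReactionDef("k1", {"A": 1}, {}, (), rate)],
        [],
        [ObservableDef("Y1", "A", ("A",))],
    )


def two_state_cycle(kf=2.0, kb=1.0, a0=1.0, b0=0.0):
    """A <-> B with conserved total."""
    return NetworkModel(
        [SpeciesDef("A", "A", a0, "IIS-mTOR", "pool"), SpeciesDef("B", "B", b0, "IIS-mTOR", "pool")],
        [ReactionDef("k1", {"A": 1}, {"B": 1}, (), kf), ReactionDef("k2", {"B": 1}, {"A": 1}, (), kb)],
        [],
        [ObservableDef("Y1", "total", ("A", "B"))],
    )


def birth_death_model(birth=5.0, death=1.0, x0=0.0):
    """0 -> A at rate birth, A -> 0 at rate death*A; stationary mean birth/death."""
    return NetworkModel(
        [SpeciesDef("A", "A", x0, "IIS-mTOR")],
        [ReactionDef("k1", {}, {"A": 1}, (), birth), ReactionDef("k2", {"A": 1}, {}, (), death)],
        [],
        [ObservableDef("Y1", "A", ("A",))],
    )


def three_species_chain():
    """A -> B -> C with feedback modifier: small model for sensitivity oracles."""
    return NetworkModel(
        [
            SpeciesDef("A", "A", 2.0, "IIS-mTOR"),
            SpeciesDef("B", "B", 0.5, "IIS-mTOR"),
            SpeciesDef("C", "C", 0.1, "IIS-mTOR"),
        ],
        [
            ReactionDef("k1", {"A": 1}, {"B": 1}, (), 0.8),
            ReactionDef("k2", {"B": 1}, {"C": 1}, (), 1.4),
            ReactionDef("k3", {"C": 1}, {}, ("B",), 0.6),
            ReactionDef("k4", {}, {"A": 1}, (), 0.3),
        ],
        [],
        [ObservableDef("Y1", "B", ("B",)), ObservableDef("Y2", "C", ("C",))],
    )
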