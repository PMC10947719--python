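import numpy as np
import pytest

from microsim.agents import Agent, MassPoint, update_geometry
from microsim.species import SpeciesLibrary


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def library():
    lib = SpeciesLibrary()
    lib.add_module(
        "coccoid",
        {
            "density": 150.0,
            "division mass": 300.0,
            "division cv": 0.1,
            "initial mass": 150.0,
        },
    )
    lib.add_species("bug", ["coccoid"])
    return lib


def make_coccus(position, mass=300.0, density=150.0, dim=None, **aspects):
    """Free-standing spherical agent with geometry consistent with its mass."""
    pos = np.asarray(position, dtype=float)
    agent = Agent(
        "bug",
        [MassPoint(pos, mass)],
        aspects={"density": density, **aspects},
    )
    update_geometry(agent)
    return agent


def make_rod(p0, p1, mass=600.0, radius=0.4, density=150.0, **aspects):
    from microsim.agents import BACILLUS

    agent = Agent(
        "bug",
        [
            MassPoint(np.asarray(p0, dtype=float), mass / 2),
            MassPoint(np.asarray(p1, dtype=float), mass / 2),
        ],
        kind=BACILLUS,
        aspects={"density": density, "rod radius": radius, **aspects},
    )
    update_geometry(agent)
    return agent
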