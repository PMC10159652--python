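import pytest

from exprflux import (
    CoreNetwork,
    Metabolite,
    Reaction,
    build_multi_tissue,
    make_toy_plant,
)


@pytest.fixture(scope="session")
def bundle():
    """One shared toy-plant fixture (seed 1, default sizes)."""
    return make_toy_plant(seed=1)


def single_copy_model(reactions, metabolite_ids):
    """A 1-tissue 1-phase model from raw reactions (ids get __t__p suffix)."""
    core = CoreNetwork(
        metabolites=[Metabolite(m) for m in metabolite_ids],
        reactions=reactions,
    )
    return build_multi_tissue(core, ["t"], ["p"], [], biomass_reaction=None)


def rid(core_id):
    return f"{core_id}__t__p"


@pytest.fixture
def chain_model():
    """SRC ->(forced 1) A -> B -> C -> SNK, no alternatives."""
    reactions = [
        Reaction("SRC", {"A": 1.0}, 1.0, 1.0),
        Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, 10.0),
        Reaction("R2", {"B": -1.0, "C": 1.0}, 0.0, 10.0),
        Reaction("SNK", {"C": -1.0}, 0.0, 10.0),
    ]
    return single_copy_model(reactions, ["A", "B", "C"])


@pytest.fixture
def parallel_model():
    """Forced unit throughput with two single-reaction routes A -> C."""
    reactions = [
        Reaction("SRC", {"A": 1.0}, 1.0, 1.0),
        Reaction("ROUTE1", {"A": -1.0, "C": 1.0}, 0.0, 10.0),
        Reaction("ROUTE2", {"A": -1.0, "C": 1.0}, 0.0, 10.0),
        Reaction("SNK", {"C": -1.0}, 0.0, 10.0),
    ]
    return single_copy_model(reactions, ["A", "C"])
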