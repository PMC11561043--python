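import pytest

from cogmap import (
    FixtureSpec,
    assign_interaction_modes,
    build_fixture,
    filter_min_residues,
    ligand_library,
    match_bound_to_cognates,
    worked_example_molecules,
)


@pytest.fixture(scope="session")
def worked():
    return worked_example_molecules()


@pytest.fixture(scope="session")
def library():
    return ligand_library()


@pytest.fixture(scope="session")
def world():
    """Default synthetic world shared by read-only tests."""
    return build_fixture(FixtureSpec(seed=11, n_structures=12))


@pytest.fixture(scope="session")
def world_interactions(world):
    return assign_interaction_modes(filter_min_residues(world.contacts))


@pytest.fixture(scope="session")
def world_matches(world):
    return match_bound_to_cognates(world.bound_molecules, world.cognates)
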