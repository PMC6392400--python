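import numpy as np
import pytest

from frphylo.design import ControlVariation, ExperimentalDesign, SpeciesInfo
from frphylo.fixtures import STUDY_CONTROL_VARIATION, study_design


@pytest.fixture(scope="session")
def design():
    return study_design()


@pytest.fixture(scope="session")
def control():
    return STUDY_CONTROL_VARIATION


@pytest.fixture
def tiny_design():
    """One familiar and one novel species, two temperatures, small grid."""
    species = (
        SpeciesInfo("Famularia una", "", "South America", "aquatic"),
        SpeciesInfo("Novella altera", "", "Europe", "aquatic"),
    )
    return ExperimentalDesign(
        n_blocks=2,
        temperatures_C=(26.0, 34.0),
        species=species,
        biomass_levels_g=(1, 4, 8, 12),
        duration_hr=60.0,
    )


@pytest.fixture
def zero_control(tiny_design):
    return ControlVariation({s.name: (0.0, 0.0) for s in tiny_design.species})


def make_uniform_species(n: int, origin: str = "South America"):
    return tuple(
        SpeciesInfo(f"Species {chr(97 + i)}", "", origin, "aquatic") for i in range(n)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
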