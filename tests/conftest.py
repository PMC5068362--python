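import numpy as np
import pandas as pd
import pytest

import commdecomp as cd


@pytest.fixture(scope="session")
def toy_traits() -> cd.TraitTable:
    """3 species, 2 axes: one binary attribute and one mensural attribute."""
    data = pd.DataFrame(
        {"diet_1": [1.0, 0.0, 0.0], "mass": [10.0, 10.0, 30.0]},
        index=["sp1", "sp2", "sp3"],
    )
    return cd.TraitTable(
        data=data,
        axis=pd.Series({"diet_1": "diet", "mass": "size"}),
        kind=pd.Series({"diet_1": "binary", "mass": "mensural"}),
        mass_attr="mass",
    )


@pytest.fixture(scope="session")
def study_pool() -> cd.SpeciesPool:
    """A 34-species pool with the 27-attribute / 7-axis trait design."""
    return cd.generate_species_pool(cd.ScenarioConfig(seed=11))


@pytest.fixture(scope="session")
def null_bundle() -> cd.SimulationBundle:
    return cd.simulate(cd.ScenarioConfig(mechanism="null", seed=5))


@pytest.fixture(scope="session")
def dispersion_bundle() -> cd.SimulationBundle:
    return cd.simulate(cd.ScenarioConfig(mechanism="dispersion_gradient", seed=5))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def predictor_blocks(bundle: cd.SimulationBundle):
    """Environment block (all env columns) and space block (first MEM)."""
    conn = cd.build_connectivity(bundle.sites)
    S = cd.PredictorSet(role="space", data=cd.mem_basis(conn).predictors(1))
    E = cd.PredictorSet(role="environment",
                        data=bundle.sites.drop(columns=["x", "y"]))
    return E, S
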