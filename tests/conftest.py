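import numpy as np
import pandas as pd
import pytest

import soilmultifun as smf


@pytest.fixture(scope="session")
def params():
    return smf.SimulationParams(seed=7)


@pytest.fixture(scope="session")
def pool():
    return smf.build_species_pool()


@pytest.fixture(scope="session")
def design(params):
    return smf.generate_design(params)


@pytest.fixture(scope="session")
def traits(pool, params):
    return smf.generate_traits(pool, params)


@pytest.fixture(scope="session")
def covers(design, params):
    return smf.generate_covers(design, params)


@pytest.fixture(scope="session")
def functions(design, params):
    return smf.generate_soil_functions(design, params)


@pytest.fixture(scope="session")
def analysis(design, covers, traits, functions):
    """Merged per-plot table: design, functions, diversity, FD, multifun."""
    diversity = smf.diversity_table(covers)
    fd_table = smf.community_fd(covers, traits)
    mf = smf.multifun.multifunctionality_table(functions)
    return design.join([functions, diversity, fd_table, mf])


def random_space(rng, n_species, n_axes=2):
    """A FunctionalSpace built directly from random Euclidean coordinates."""
    import soilmultifun.fd as fdmod

    coords = rng.normal(size=(n_species, n_axes))
    names = [f"sp{i:02d}" for i in range(n_species)]
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    return fdmod.FunctionalSpace(
        distances=pd.DataFrame(d, index=names, columns=names),
        coordinates=pd.DataFrame(
            coords, index=names, columns=[f"axis{i+1}" for i in range(n_axes)]
        ),
        eigenvalues=np.ones(n_axes),
    )
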