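import numpy as np
import pytest

import deerscr


@pytest.fixture(scope="session")
def paper_traps():
    """The 92-plot clustered design preset."""
    return deerscr.gen_design()


@pytest.fixture(scope="session")
def paper_space(paper_traps):
    return deerscr.build_state_space(paper_traps, buffer_m=1000.0, resolution_m=120.0)


@pytest.fixture(scope="session")
def paper_landscape(paper_traps, paper_space):
    """Seeded landscape with habitat and distance covariates attached."""
    from deerscr import landscape as ls

    raster, features = deerscr.gen_landscape(paper_traps, rng=1)
    space = deerscr.build_state_space(paper_traps)
    space.habitat = ls.aggregate_majority(raster, space)
    space.dist_artificial = ls.distance_to_feature(space.coords(), features["artificial"])
    space.dist_water = ls.distance_to_feature(space.coords(), features["water"])
    traps = deerscr.gen_design()
    traps.habitat = np.array([
        ls.assign_trap_habitat((x, y), raster) for x, y in zip(traps.x, traps.y)
    ])
    traps.dist_agricultural = ls.distance_to_feature(traps.coords(), features["agricultural"])
    traps.dist_artificial = ls.distance_to_feature(traps.coords(), features["artificial"])
    traps.dist_water = ls.distance_to_feature(traps.coords(), features["water"])
    return raster, features, space, traps
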