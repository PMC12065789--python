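import warnings

import pytest

from memscreen import design, structure_feats, synthetic_data


@pytest.fixture(scope="session")
def grid():
    return design.default_grid()


@pytest.fixture(scope="session")
def small_landscape(grid):
    cfg = synthetic_data.LandscapeConfig(n_proteins=3, grid=grid, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synthetic_data.gen_yield_landscape(
            cfg, design=design.gsd(grid, 3)
        )


@pytest.fixture(scope="session")
def bundle4():
    cfg = synthetic_data.BundleConfig(
        n_helices=4, helix_length=30, ring_radius=8.0, seed=11
    )
    return synthetic_data.gen_helix_bundle(cfg)


@pytest.fixture(scope="session")
def structure4(bundle4):
    return structure_feats.annotated_from_bundle(bundle4)
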