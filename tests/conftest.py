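import numpy as np
import pandas as pd
import pytest

import opspheno as op


@pytest.fixture(scope="session")
def small_library() -> pd.DataFrame:
    return op.make_guide_library(6, 4, 5)


@pytest.fixture(scope="session")
def null_screen(small_library):
    """A small screen with no planted effects."""
    spec = op.EffectSpec(cells_per_guide=40, unmapped_fraction=0.0)
    return op.simulate_screen(small_library, spec, n_fov=8, seed=101)


@pytest.fixture(scope="session")
def effect_screen():
    """A screen with three strong planted hits, one per effect class."""
    lib = op.make_guide_library(12, 4, 10)
    hits = {
        "GENE0001": op.GeneEffect("toward_unstim", 4.0, (1.0, 1.0, 0.5, 0.0)),
        "GENE0002": op.GeneEffect("toward_5h", 4.0, (1.0, 1.0, 0.5, 0.0)),
        "GENE0003": op.GeneEffect("novel", 4.0, (1.0, 1.0, 0.5, 0.0)),
    }
    spec = op.EffectSpec(hit_genes=hits, cells_per_guide=50, unmapped_fraction=0.0)
    return op.simulate_screen(lib, spec, n_fov=10, seed=202), lib


@pytest.fixture(scope="session")
def normalized_effect_cells(effect_screen):
    screen, lib = effect_screen
    cells = op.filter_cells(screen.cells, lib)
    return op.normalize_per_fov(cells)


@pytest.fixture(scope="session")
def golgi_fixture():
    """Two-channel image: bright Golgi disks over dim cytoplasm blobs.

    Five final objects are expected: four isolated bright disks, one
    merged close pair; a small bright decoy is below the area filter and
    dim blobs belong to the intermediate intensity class.
    """
    bright = [
        ((100, 100), 20, 200.0, 120.0),
        ((100, 300), 25, 200.0, 90.0),
        ((300, 100), 22, 200.0, 150.0),
        ((330, 330), 30, 200.0, 60.0),
        ((430, 200), 18, 200.0, 100.0),  # pair part A
        ((430, 245), 18, 200.0, 100.0),  # pair part B, 9 px edge gap
        ((250, 430), 12, 200.0, 80.0),   # 441 px decoy
    ]
    dim = [((60, 430), 35, 50.0, 20.0), ((460, 60), 40, 50.0, 20.0), ((200, 250), 30, 50.0, 20.0)]
    noise_sd = 2.0
    gm, st, truth = op.make_synthetic_golgi_image(
        bright + dim, (512, 512), background=0.0, noise_sd=noise_sd, seed=404
    )
    return gm, st, truth, noise_sd
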