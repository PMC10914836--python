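import numpy as np
import pytest

import slidemil as sm


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 30-slide cohort on 4x4 grids of 16 px tiles: fast shared fixture."""
    spec = sm.CohortSpec(
        n_slides=30, grid_rows=4, grid_cols=4, tile_px=16,
        annotated_fraction=0.2, seed=11,
    )
    root = tmp_path_factory.mktemp("small_cohort")
    return sm.generate_cohort(spec, root)


@pytest.fixture(scope="session")
def separable_tiles():
    """Labelled tiles at full separability, balanced over the three classes."""
    rng = np.random.default_rng(5)
    tiles, labels = [], []
    for cls in (1, 2, 3):
        for _ in range(20):
            tiles.append(sm.render_tile(cls, 32, rng, separability=1.0))
            labels.append(cls)
    return np.stack(tiles), np.asarray(labels)


@pytest.fixture(scope="session")
def trained_scorer(separable_tiles):
    tiles, labels = separable_tiles
    return sm.supervised_fit(tiles, labels, epochs=30, seed=3)


@pytest.fixture(scope="session")
def default_cohort(tmp_path_factory):
    """The default desk-scale study cohort (150 slides, 8x8 grid, 32 px,
    separability 0.8, 9% annotated) used by the end-to-end checks."""
    root = tmp_path_factory.mktemp("default_cohort")
    return sm.generate_cohort(sm.CohortSpec(seed=0), root)


@pytest.fixture(scope="session")
def default_bags(default_cohort):
    return {
        "train": sm.bags_from_manifest(default_cohort, "train"),
        "val": sm.bags_from_manifest(default_cohort, "val"),
        "test": sm.bags_from_manifest(default_cohort, "test"),
    }


@pytest.fixture(scope="session")
def default_pretrained(default_bags):
    tiles, labels = sm.annotated_tiles(default_bags["train"])
    return sm.supervised_fit(tiles, labels, seed=0)
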