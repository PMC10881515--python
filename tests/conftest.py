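import warnings

import numpy as np
import pytest

from morphoprof import (
    ExperimentConfig,
    build_cell_index,
    generate_experiment,
    load_crops,
)

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def tiny_config():
    """Small but complete experiment: 2 plates, 4 treatments in 2 MoA classes."""
    return ExperimentConfig(
        n_plates=2,
        wells_per_plate=10,
        sites_per_well=1,
        n_treatments=4,
        n_moa_classes=2,
        replicates_per_treatment=2,
        cells_per_site_mean=8.0,
        image_shape=(96, 96),
        crop_size=32,
        effect_sizes=(0.5, 1.0, 1.5, 2.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_bundle(tiny_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("tiny_bundle")
    return generate_experiment(tiny_config, out)


@pytest.fixture(scope="session")
def tiny_cells(tiny_bundle):
    return build_cell_index(tiny_bundle)


@pytest.fixture(scope="session")
def tiny_crops(tiny_bundle, tiny_cells):
    return load_crops(tiny_bundle, tiny_cells, crop_size=32)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
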