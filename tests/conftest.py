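import numpy as np
import pytest

from budl import (
    CostConfig,
    SyntheticSpec,
    make_fitness,
    make_synthetic_features,
    make_synthetic_images,
    stratified_holdout,
)


@pytest.fixture(scope="session")
def small_table():
    """Separable 3-class table, d=16, with planted truth for quick wrapper runs."""
    spec = SyntheticSpec(
        n_per_class=(20, 20, 20), d_total=16, k_informative=4, separation=2.0, seed=11
    )
    table, truth = make_synthetic_features(spec)
    return table, truth


@pytest.fixture(scope="session")
def small_split(small_table):
    table, _ = small_table
    return stratified_holdout(table.labels, 0.2, seed=11)


@pytest.fixture(scope="session")
def small_fitness(small_table, small_split):
    table, _ = small_table
    return make_fitness(table, small_split, CostConfig())


@pytest.fixture(scope="session")
def toy_image_dir(tmp_path_factory):
    root = tmp_path_factory.mktemp("toy_images")
    make_synthetic_images((4, 3, 3), root, size=64, seed=5)
    return root
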