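import numpy as np
import pytest

from sadasnet.architecture import decode, repair
from sadasnet.data import SyntheticSpec, generate_synthetic
from sadasnet.search_space import SearchSpace, build_layout, random_genome


@pytest.fixture(scope="session")
def small_layout():
    return build_layout(SearchSpace.small())


@pytest.fixture(scope="session")
def default_layout():
    return build_layout(SearchSpace())


@pytest.fixture(scope="session")
def tiny_dataset():
    """4 well-separated classes, 16x16, 30 images each."""
    return generate_synthetic(
        SyntheticSpec(n_classes=4, image_size=16, per_class_counts=(30,) * 4, seed=0)
    )


@pytest.fixture(scope="session")
def separable_2class():
    """Near-noise-free 2-class set a tiny net should learn almost perfectly."""
    return generate_synthetic(
        SyntheticSpec(
            n_classes=2, image_size=12, per_class_counts=(60, 60),
            noise_sigma=2.0, separability=1.0, seed=3,
        )
    )


def random_repaired(layout, input_shape, num_classes, seed):
    rng = np.random.default_rng(seed)
    arch = decode(random_genome(layout, rng), layout, input_shape, num_classes)
    arch, _ = repair(arch)
    return arch
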