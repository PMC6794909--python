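import numpy as np
import pytest

from morphohybrid import GeneratorSpec, generate_study, gpa


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def small_spec(**overrides) -> GeneratorSpec:
    """A compact two-bone study used across tests; override freely."""
    base = dict(
        bones={"humerus": 8, "femur": 8},
        n_per_group={"donkey": 15, "horse": 15, "hybrid": 12},
        n_mules=7,
        seed=1,
    )
    base.update(overrides)
    return GeneratorSpec(**base)


@pytest.fixture
def small_study():
    return generate_study(small_spec())


@pytest.fixture
def aligned_humerus(small_study):
    dataset, _ = small_study
    return gpa(dataset.configurations_for_bone("humerus"), bone_id="humerus")


def random_config(rng, k=7, scale=1.0):
    return scale * rng.standard_normal((k, 3))
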