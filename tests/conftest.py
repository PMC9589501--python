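import numpy as np
import pytest

from stressfeat import StressSimSpec, build_feature_matrix, gen_stress_field
from stressfeat.stress import NodeSubsetSpec

PLANTED_BONES = ("MP4", "PP2")


@pytest.fixture(scope="session")
def planted_fields():
    """Default-scale field pair with two bones tail-shifted x1.5."""
    spec = StressSimSpec(effect_map={b: 1.5 for b in PLANTED_BONES}, seed=0)
    return gen_stress_field(spec)


@pytest.fixture(scope="session")
def planted_fm(planted_fields):
    """Sampled top-200 feature matrix with planted effects (400 instances)."""
    fa, fb = planted_fields
    return build_feature_matrix(fa, fb, NodeSubsetSpec.from_case(200),
                                summary="sampled", seed=0)


@pytest.fixture(scope="session")
def null_fields():
    """Default-scale field pair with no planted effects."""
    return gen_stress_field(StressSimSpec(seed=0))


@pytest.fixture(scope="session")
def null_fm(null_fields):
    fa, fb = null_fields
    return build_feature_matrix(fa, fb, NodeSubsetSpec.from_case(200),
                                summary="sampled", seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
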