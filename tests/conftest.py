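import pytest

from coalboot.demography import (
    build_limenitis_models,
    get_model,
    limenitis_sampling,
    to_coalescent_scale,
)
from coalboot.hyptest import limenitis_hypothesis_pair


@pytest.fixture(scope="session")
def models():
    return build_limenitis_models()

@pytest.fixture(scope="session")
def models_by_id(models):
    return {m.model_id: m for m in models}


@pytest.fixture(scope="session")
def sampling():
    return limenitis_sampling()


@pytest.fixture(scope="session")
def pair():
    return limenitis_hypothesis_pair()


@pytest.fixture(scope="session")
def scaled_r2():
    return to_coalescent_scale(get_model("R2"))


@pytest.fixture(scope="session")
def scaled_mm1():
    return to_coalescent_scale(get_model("MM1"))
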