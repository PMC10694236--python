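import pytest

from sulfurgem.fba import Medium
from sulfurgem.sulfur import build_sulfur_core
from sulfurgem.synth import SyntheticSpec, generate_toy_model


@pytest.fixture(scope="session")
def sulfur_core():
    """The bundled sulfur-oxidation core (incomplete-CBB build), read-only."""
    return build_sulfur_core()


@pytest.fixture()
def toy_model():
    return generate_toy_model(SyntheticSpec(10, 14, seed=1))


@pytest.fixture()
def toy_spec():
    return SyntheticSpec(10, 14, seed=1)


@pytest.fixture()
def toy_base_medium():
    """Carbon-source-test medium for toy models: native substrate closed."""
    return Medium(closed={"EX_sub_e"})
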