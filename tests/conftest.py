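import pytest

from readacross import SyntheticSpec, build_test_set, build_training_set, generate


@pytest.fixture(scope="session")
def synth():
    """Default synthetic two-database study (seed 0)."""
    return generate(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def synth_training(synth):
    a, b, _ = synth
    return build_training_set(a, b)


@pytest.fixture(scope="session")
def synth_test(synth):
    a, b, _ = synth
    return build_test_set(a, b)
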