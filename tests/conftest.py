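import pytest

from isomob import default_site_registry, generate_study_like


@pytest.fixture(scope="session")
def registry():
    return default_site_registry()


@pytest.fixture(scope="session")
def study_like():
    """The bundled ten-community synthetic scenario under a fixed seed."""
    samples, truth, registry = generate_study_like(1)
    return samples, truth, registry
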