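import pytest

from vtecea import default_parameters


@pytest.fixture(scope="session")
def defaults():
    return default_parameters()


@pytest.fixture()
def perturbed(defaults):
    """A jittered but valid parameter set, away from the published inputs."""
    from vtecea import generate_fixture

    return generate_fixture(defaults, perturbation=0.1, seed=42)
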