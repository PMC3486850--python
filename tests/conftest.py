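import pytest
from hypothesis import settings

from minisatkit.synthetic import default_arms

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def arms():
    """Four metacentric synthetic chromosomes, eight 50-Mb arms."""
    return default_arms(n_chroms=4, arm_length=50_000_000)
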