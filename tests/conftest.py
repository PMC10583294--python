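import pytest
from hypothesis import settings

from flipcorr import RateParams, params_from_observables

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base() -> RateParams:
    """Canonical noiseless ground truth: P0=0.3, tau=50, A=1."""
    return params_from_observables(P0=0.3, tau=50.0, A=1.0)
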