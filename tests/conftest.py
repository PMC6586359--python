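import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def basis_p1():
    from ldmoments.basis import build_basis

    return build_basis(["anc"])


@pytest.fixture(scope="session")
def basis_p2():
    from ldmoments.basis import build_basis

    return build_basis(["pop1", "pop2"])
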