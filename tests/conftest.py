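import numpy as np
import pytest

from rppclc import FamilySpec, ProviderSummary


@pytest.fixture
def fam_poisson():
    return FamilySpec("poisson")


@pytest.fixture
def fam_normal():
    return FamilySpec("normal", 1.0)


def make_provider(id="P1", O=10.0, E=10.0, n_tilde=None, W=(0.0,), sum_b3=None):
    return ProviderSummary(
        id=id,
        O=O,
        E=E,
        n_tilde=E if n_tilde is None else n_tilde,
        W=np.asarray(W, dtype=float),
        sum_b3=sum_b3,
    )


@pytest.fixture
def provider_factory():
    return make_provider
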