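import numpy as np
import pytest

from dirscan import resources


@pytest.fixture(scope="session")
def profiles():
    """Calibrated packaged domain profiles (built once per session)."""
    return resources.default_profiles()


@pytest.fixture(scope="session")
def consensi():
    return {k: resources.domain_consensus(k) for k in ("RT", "YR", "MT")}


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_101)
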