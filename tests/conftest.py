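import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from bigsol import load_big31, load_big31_reference_frame


@pytest.fixture(scope="session")
def big31():
    """The packaged 31-compound big-molecule table as (record, entry) pairs."""
    return load_big31()


@pytest.fixture(scope="session")
def big31_records(big31):
    return [r for r, _ in big31]


@pytest.fixture(scope="session")
def big31_obs(big31):
    return np.array([e.log_s0 for _, e in big31])


@pytest.fixture(scope="session")
def reference(big31):
    """Reference prediction table aligned with the property fixture."""
    frame = load_big31_reference_frame()
    assert list(frame["id"]) == [r.id for r, _ in big31]
    return frame
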