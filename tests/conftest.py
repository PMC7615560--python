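import numpy as np
import pytest

from betabarcode.sessions import SessionSpec, generate_session


@pytest.fixture(scope="session")
def short_session():
    """One seeded session with short (60-s) stages; shared across test modules."""
    spec = SessionSpec(duration_s=60.0, seed=7)
    rec, gt = generate_session(spec)
    return spec, rec, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
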