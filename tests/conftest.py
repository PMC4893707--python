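import numpy as np
import pytest

from swdmaps.synth_lfp import SessionConfig


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def fast_session_config():
    """Short low-rate session at a reduced sampling rate for quick tests."""
    return SessionConfig(fs=250.0, duration_s=300.0, seed=0)


def fast_config(**kw):
    """SessionConfig at 250 Hz with overridable fields (factory for tests)."""
    kw.setdefault("fs", 250.0)
    kw.setdefault("duration_s", 300.0)
    kw.setdefault("seed", 0)
    return SessionConfig(**kw)
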