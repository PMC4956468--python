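import numpy as np
import pytest

from gatecycle import GatingScheme


@pytest.fixture
def flicker_scheme():
    """Fast-flicker scheme with P_o near one half."""
    return GatingScheme(1.0, 1.0, 2.0, 100.0)


@pytest.fixture
def slow_scheme():
    """Low-P_o scheme with ~10 ms flickers and ~2 s bursts."""
    return GatingScheme(0.1, 0.5, 2.0, 100.0)


@pytest.fixture
def no_flicker_scheme():
    """Effectively two-state C-O scheme (flicker entry negligible)."""
    return GatingScheme(1.0, 2.0, 1e-9, 100.0)
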