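import numpy as np
import pytest

from stellate.models import build_sc_cell, run_step


@pytest.fixture(scope="session")
def sc_cell():
    """Reference optimized stellate cell (session-shared, read-only)."""
    return build_sc_cell()


@pytest.fixture(scope="session")
def spontaneous_trace(sc_cell):
    """2-s spontaneous run on the reference cell (expensive, shared)."""
    return run_step(sc_cell, 0.0, duration_ms=2000.0, pre_ms=500.0, post_ms=0.0)


@pytest.fixture(scope="session")
def hyperpol_trace(sc_cell):
    """-16 pA, 2-s step with post window for rebound (shared)."""
    return run_step(sc_cell, -16.0, duration_ms=2000.0, pre_ms=500.0, post_ms=800.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
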