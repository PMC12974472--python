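import numpy as np
import pytest

from ligfid.mechanism import KineticScheme, scheme_from_steady_state


@pytest.fixture
def wt_scheme() -> KineticScheme:
    """Ground-truth scheme mirroring wild-type canonical-substrate kinetics."""
    return scheme_from_steady_state(0.52, 100.0, 0.10)


@pytest.fixture
def abortive_scheme() -> KineticScheme:
    """Scheme with a dominant abortive branch (mostly AMP-DNA release)."""
    return scheme_from_steady_state(0.00608, 345.0, 0.93)


@pytest.fixture
def substrate_grid() -> np.ndarray:
    return np.array([25.0, 50.0, 100.0, 200.0, 400.0, 800.0])
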