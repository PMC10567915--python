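import numpy as np
import pytest

import mrsquant as mq
from mrsquant.fitting import PriorConstraint


@pytest.fixture(scope="session")
def p_acq():
    return mq.phosphorus_acquisition()


@pytest.fixture(scope="session")
def h_acq():
    return mq.proton_acquisition()


@pytest.fixture(scope="session")
def p_truth():
    """Default phosphorus ground-truth model."""
    return mq.default_phosphorus_model()


@pytest.fixture(scope="session")
def p_prior(p_truth):
    """Prior-knowledge starting model: prior shifts, nominal amplitudes, zero phase."""
    return [mq.ResonanceSpec(r.name, r.shift_ppm, 1.0, r.damping_hz, 0.0, r.multiplet)
            for r in p_truth]


@pytest.fixture(scope="session")
def p_constraints(p_truth):
    """AMARES-style prior knowledge: fixed phases, fixed macromolecular position."""
    cons = [PriorConstraint(r.name, "phase", "fix", 0.0) for r in p_truth]
    cons += [PriorConstraint("MM", "damping", "fix", 200.0),
             PriorConstraint("MM", "shift", "fix", 2.0)]
    return cons


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
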