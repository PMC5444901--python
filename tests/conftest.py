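"""Shared fixtures: a default synthetic recording and its detection outputs.

Session-scoped so the 600 s ground-truth simulation and the full LFP
detection pipeline run once and are shared by the detection, locking and
acceptance tests.
"""

import numpy as np
import pytest

from slowwave import detect as det
from slowwave.simulate import StateSequenceParams, simulate

DEFAULT_SEED = 42


@pytest.fixture(scope="session")
def ground_truth():
    """Default 600 s entrained-mode recording."""
    return simulate(StateSequenceParams(total_dur=600.0), seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def vm_truth(ground_truth):
    """Ground-truth segmentation detected from the membrane potential."""
    return det.detect_states_vm(ground_truth.vm)


@pytest.fixture(scope="session")
def lfp_detection(ground_truth, vm_truth):
    """Full LFP detection output: (segmentation, decisions, gmm, tables)."""
    return det.detect_states_lfp(ground_truth.lfp, vm_truth, seed=0)


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test: no cross-test order coupling."""
    return np.random.default_rng(DEFAULT_SEED)
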