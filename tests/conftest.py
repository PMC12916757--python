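"""Shared fixtures: small pre-built morphologies and cached simulation grids.

The heavier grids (used by the acceptance-level tests) are session-scoped so
they are simulated once per test run.
"""

import numpy as np
import pytest

from tacsim.circuit import CircuitSpec
from tacsim.morphology import build_reduced_morphology
from tacsim.protocol import StimulusProtocol
from tacsim.analysis import run_condition_grid


@pytest.fixture(scope="session")
def l5_morphology():
    return build_reduced_morphology("L5_PC")


@pytest.fixture(scope="session")
def ngc_morphology():
    return build_reduced_morphology("L1_NGC")


@pytest.fixture(scope="session")
def alpha_rate_records():
    """Connected alpha circuit, 0 vs 2 mA, 5 paired trials, 6-s window."""
    spec = CircuitSpec(condition="alpha", connected=True)
    proto = StimulusProtocol.desk_scale(10.0, base_seed=0,
                                        amplitudes=(0.0, 2.0), n_trials=5)
    return run_condition_grid(spec, proto)


@pytest.fixture(scope="session")
def alpha_plv_records():
    """Connected alpha circuit, 5 amplitudes x 5 trials, 10-s active window."""
    spec = CircuitSpec(condition="alpha", connected=True)
    proto = StimulusProtocol(pre_ms=1000.0, stim_ms=10000.0, post_ms=1000.0,
                             amplitudes_ma=(0.4, 0.8, 1.2, 1.6, 2.0),
                             freq_hz=10.0, n_trials=5, base_seed=0)
    return run_condition_grid(spec, proto)
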