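import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _cme oracle helper

from coldshock.stochastic import RateSet, SimulationConfig


@pytest.fixture
def fast_rates():
    """Fast-relaxing one-step rates (stationary mean protein = 20)."""
    return RateSet(k1=0.1, k2=0.05, lambda1=0.05, lambda2=0.005)


@pytest.fixture
def fast_config():
    """Small but well-equilibrated ensemble for fast-relaxing rates."""
    return SimulationConfig(horizon=2e4, n_runs=20, sample_interval=200.0,
                            seed=11)
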