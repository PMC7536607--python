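import pytest

import trailbells.engine
import trailbells.layout
from trailbells.engine import EngineConfig, run_trace

# domain classes whose names start with "Test" are not pytest suites
trailbells.engine.TestEvent.__test__ = False
trailbells.layout.TestLayout.__test__ = False
from trailbells.layout import make_bells_layout, make_tmt_layout
from trailbells.simulator import SimProfile, simulate_bells, simulate_tmt


@pytest.fixture(scope="session")
def tmt_a():
    return make_tmt_layout("A", "it", seed=7)


@pytest.fixture(scope="session")
def tmt_b_en():
    return make_tmt_layout("B", "en", seed=7)


@pytest.fixture(scope="session")
def bells():
    return make_bells_layout(seed=1)


@pytest.fixture(scope="session")
def tmt_session(tmt_a):
    """One simulated TMT-A session with errors and repetitions, plus its log."""
    res = simulate_tmt(tmt_a, SimProfile(error_prob=0.15, repetition_prob=0.1, seed=42))
    log = run_trace(tmt_a, res.samples, declarations=res.declarations)
    return res, log


@pytest.fixture(scope="session")
def bells_session(bells):
    res = simulate_bells(
        bells,
        SimProfile(inter_target_mean_s=3.0, error_prob=0.1, scan_irregularity=0.4, seed=42),
    )
    log = run_trace(bells, res.samples, declarations=res.declarations)
    return res, log
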