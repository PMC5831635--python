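import numpy as np
import pytest

from per2as import simulate, summarize_limit_cycle, wt_parameters


@pytest.fixture(scope="session")
def wt():
    return wt_parameters()


@pytest.fixture(scope="session")
def wt_pre_traj(wt):
    """Wild-type pre-transcriptional attractor (300 h window at 0.1 h)."""
    return simulate("pre", wt, t_end=800.0, transient=500.0, dt=0.1)


@pytest.fixture(scope="session")
def wt_summary(wt_pre_traj):
    return summarize_limit_cycle(wt_pre_traj)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
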