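import numpy as np
import pytest

from circuitnoise import NetworkSpec, SimConfig, Trajectory, build_network


@pytest.fixture(scope="session")
def toy_trajectory_factory():
    """Build a Trajectory from a raw P series (for summary-level tests)."""

    def make(p_series, record_interval=1.0, burn_in=0.0):
        p = np.asarray(p_series)
        n = p.size
        counts = np.zeros((n, 10), dtype=np.int64)
        counts[:, 6] = p  # species P
        network = build_network("constitutive")
        config = SimConfig(duration=(n - 1) * record_interval or record_interval,
                           record_interval=record_interval, burn_in=burn_in, seed=0)
        return Trajectory(times=np.arange(n) * record_interval, counts=counts,
                          factors=np.ones(n), network=network, config=config)

    return make
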