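import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=20,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from qtrap import synthetic
from qtrap.constants import kt
from qtrap.io_tables import WorkTrace


@pytest.fixture(scope="session")
def double_well():
    """3 kT double well with wells at 1 and 3 Å (the recovery benchmark)."""
    return synthetic.DoubleWellPotential(1.0, 3.0, 3.0 * kt(310.0))


@pytest.fixture(scope="session")
def pulling_ensemble(double_well):
    """200 stiff-spring pulls over the double well, slow schedule."""
    spec = synthetic.LangevinSpec(
        friction=1.0, timestep=2e-4, spring_k=300.0,
        schedule=(0.5, 3.5, 6.0), n_traj=200, seed=7, equil_time=0.5,
    )
    return synthetic.simulate_pulling(double_well, spec, output_every=20)


@pytest.fixture
def small_traces():
    """Three tiny hand-buildable work traces sharing one schedule."""
    t = np.linspace(0.0, 1.0, 21)
    c = np.linspace(10.0, 12.0, 21)
    traces = []
    for i, slope in enumerate((0.5, 1.0, 1.5)):
        w = slope * (c - c[0])
        traces.append(WorkTrace(f"t{i}", t, c, c - 0.05, w))
    return traces
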