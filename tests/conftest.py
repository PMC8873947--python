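import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dblsim as ds
from dblsim.analysis import extract_features
from dblsim.protocols import run_sweep, StepProtocol

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SWEEP = StepProtocol(amplitudes_nA=(0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4))


@pytest.fixture(scope="session")
def cell():
    return ds.default_cell()


@pytest.fixture(scope="session")
def conv_cell():
    return ds.conventional_cell()


@pytest.fixture(scope="session")
def sweep_cell1(cell):
    """Current-step sweep of the fitted model, first parameter set."""
    return run_sweep(cell, SWEEP, mechanism=ds.CELL_203030003_R)


@pytest.fixture(scope="session")
def sweep_cell2(cell):
    return run_sweep(cell, SWEEP, mechanism=ds.CELL_170518_4E)


@pytest.fixture(scope="session")
def sweep_fixed(cell):
    """Same sweep with the mechanism disabled (fixed-parameter model)."""
    return run_sweep(cell, SWEEP, mechanism=None)


@pytest.fixture(scope="session")
def features_cell1(sweep_cell1):
    return [extract_features(r.soma_trace()) for r in sweep_cell1]


def amp_index(amplitude: float) -> int:
    return list(SWEEP.amplitudes_nA).index(amplitude)
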