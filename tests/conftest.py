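import numpy as np
import pytest

import pogo


@pytest.fixture(scope="session")
def nominal_params():
    return pogo.ModelParams.nominal()


@pytest.fixture(scope="session")
def fast_config():
    """Small but converged transcription for cheap tests."""
    return pogo.TranscriptionConfig(n_starts=1, n_nodes=24)


@pytest.fixture(scope="session")
def default_config():
    return pogo.TranscriptionConfig(n_starts=1)


@pytest.fixture(scope="session")
def nominal_solution(nominal_params, default_config):
    """Converged unified-nominal gait at 3 m/s, 2.94 Hz."""
    return pogo.solve_stance(nominal_params, pogo.GaitTask(v=3.0, f=2.94),
                             default_config)


@pytest.fixture(scope="session")
def nominal_audit(nominal_solution):
    return pogo.energy_audit(nominal_solution)


@pytest.fixture(scope="session")
def fast_solution(nominal_params, fast_config):
    return pogo.solve_stance(nominal_params, pogo.GaitTask(v=3.0, f=2.94),
                             fast_config)


@pytest.fixture(scope="session")
def speed_sweep_result(nominal_params, default_config):
    """Nine-point speed sweep, 2-4 m/s, preferred step frequency."""
    return pogo.speed_sweep(nominal_params, np.linspace(2.0, 4.0, 9),
                            config=default_config)


@pytest.fixture(scope="session")
def slope_study_result(nominal_params, default_config):
    """Slope sweep at 3 m/s, 2.94 Hz, grades -0.20 to +0.10."""
    return pogo.slope_study(nominal_params, v=3.0, f=2.94,
                            config=default_config)
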