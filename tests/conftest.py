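import numpy as np
import pytest

from moodcycles import ModelParams, SolverOptions, State, constant_reality, simulate


@pytest.fixture(scope="session")
def canonical_params():
    """Symmetric subthreshold parameter set (eta_v = k = 0.37, f = 0.3)."""
    return ModelParams.from_ratios(0.3)


@pytest.fixture(scope="session")
def bipolar_params():
    """Symmetric supra-threshold set: f*eta_m = 1.5*(eta_v + k)."""
    return ModelParams.from_ratios(1.5)


@pytest.fixture(scope="session")
def fast_opts():
    """Loose-but-adequate solver options for quick unit tests."""
    return SolverOptions(rel_tol=1e-7, abs_tol=1e-9, output_grid_spacing=0.1)


@pytest.fixture(scope="session")
def bipolar_trajectory(bipolar_params, fast_opts):
    """A converged 200-week bipolar limit-cycle run from (0, -1)."""
    return simulate(
        bipolar_params, constant_reality(0.0, 200.0), State(0.0, -1.0), 200.0, fast_opts
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180612)
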