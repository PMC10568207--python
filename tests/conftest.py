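import numpy as np
import pytest

from rnacycle.kinetics import PhaseGrid, RateProfiles, simulate_total_profiles
from rnacycle.synthetic import SineTarget, three_case_scenarios


@pytest.fixture(scope="session")
def grid500():
    return PhaseGrid(n_points=500, period_hours=19.33)


@pytest.fixture(scope="session")
def grid200():
    return PhaseGrid(n_points=200, period_hours=19.33)


@pytest.fixture(scope="session")
def sine_target():
    return SineTarget(mean=20.0, amplitude=8.0)


@pytest.fixture(scope="session")
def three_cases(grid500):
    """The three regulatory regimes sharing m(Φ) = 20 + 8 sin Φ."""
    return three_case_scenarios(grid500)


@pytest.fixture(scope="session")
def three_case_totals(three_cases, grid500):
    """Converged periodic (p, m, n_cycles) per case."""
    return {
        name: simulate_total_profiles(rates, grid500, rel_tol=1e-6)
        for name, rates in three_cases.items()
    }


@pytest.fixture(scope="session")
def dynamic_full_rates(grid500):
    """All-dynamic ground truth for full-model estimator checks."""
    ph = grid500.phases
    return RateProfiles(
        grid500,
        alpha=10.0 * (1.0 + 0.3 * np.sin(ph)),
        beta=12.0 * (1.0 + 0.2 * np.sin(ph + 0.5)),
        gamma=0.5 * (1.0 + 0.3 * np.sin(ph + 1.0)),
    )
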