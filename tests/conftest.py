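import numpy as np
import pytest

from pod12risk import CohortSpec, SeriesSpec, simulate_cohort, simulate_series


@pytest.fixture(scope="session")
def study_confusion_counts():
    """High/low score vs POD12 counts of the 63-patient validation:
    37 high-score patients of whom 26 progressed, 26 low-score of whom 3."""
    return dict(tp=26, fp=11, fn=3, tn=23)


@pytest.fixture(scope="session")
def large_cohort():
    return simulate_cohort(CohortSpec(n=5000, seed=11))


@pytest.fixture(scope="session")
def sine_series():
    """Noiseless offset sine, 25 samples short of 1000, period 40."""
    t = np.arange(1000)
    return 2.0 + np.sin(2 * np.pi * t / 40)


@pytest.fixture(scope="session")
def lorenz_series():
    panel = simulate_series(SeriesSpec(system="lorenz", n_points=5000,
                                       variables=("X",), seed=2))
    return panel.values["X"].to_numpy()


@pytest.fixture(scope="session")
def logistic_map_series():
    panel = simulate_series(SeriesSpec(system="logistic_map", n_points=2000,
                                       variables=("X",), seed=2))
    return panel.values["X"].to_numpy()
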