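import numpy as np
import pytest

from respwave import (
    NCCSeries,
    SimulationConfig,
    cwt,
    make_frequency_grid,
    score_series,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def default_grid():
    return make_frequency_grid()


@pytest.fixture(scope="session")
def default_cohort():
    """The default seeded 10-subject cohort (one normal + one LF period each)."""
    return simulate_cohort(SimulationConfig())


@pytest.fixture(scope="session")
def cohort_spectrograms(default_cohort, default_grid):
    return [cwt(sig, default_grid) for sig in default_cohort]


def pooled_series(spectrograms, td: float) -> NCCSeries:
    """Per-period NCC series pooled over all cohort spectrograms."""
    entries = []
    for spec in spectrograms:
        entries.extend(score_series(spec, td).entries)
    entries.sort(key=lambda e: e[0])
    return NCCSeries(entries=entries, duration=td)


@pytest.fixture(scope="session")
def cohort_series_td90(cohort_spectrograms):
    return pooled_series(cohort_spectrograms, 90.0)


def rel_err(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b) / np.linalg.norm(b))
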