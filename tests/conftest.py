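import numpy as np
import pytest

from gridhotspots import (
    GridLattice,
    SimulationConfig,
    SourceSchedule,
    queen_neighbors,
)


@pytest.fixture
def full_3x3():
    lattice = GridLattice(3, 3, np.ones((3, 3), bool))
    return lattice, queen_neighbors(lattice)


@pytest.fixture
def recovery_config():
    """Three-regime planted-source study: 60x60, 12 years, iid SD-5 noise.

    One always-on source (consistent), one active only the late half
    (emerging), one active only the early half (declining); amplitude 15,
    three times the noise SD.
    """
    return SimulationConfig(
        n_rows=60,
        n_cols=60,
        n_years=12,
        base_level=40.0,
        spatial_corr_length=0.0,
        noise_sd=5.0,
        sources=(
            SourceSchedule(center=(15, 15), radius=2, amplitude=15.0, active_years=frozenset(range(1, 13))),
            SourceSchedule(center=(15, 45), radius=2, amplitude=15.0, active_years=frozenset(range(7, 13))),
            SourceSchedule(center=(45, 30), radius=2, amplitude=15.0, active_years=frozenset(range(1, 7))),
        ),
        seed=20260919,
    )


@pytest.fixture
def random_masked_lattice():
    rng = np.random.default_rng(42)
    valid = rng.random((20, 20)) > 0.1
    return GridLattice(20, 20, valid)
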