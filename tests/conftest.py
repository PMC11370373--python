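import numpy as np
import pytest

from kernelds import SimulationConfig, simulate_unit
from kernelds.density import TestUnit as ExpressionUnit


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_unit(rng):
    """4+4 subjects, 60 cells each, no group effect."""
    cfg = SimulationConfig(subjects_per_group=4, cells_per_subject_per_cluster=60)
    unit, _ = simulate_unit("null", cfg, unit_seed=11)
    return unit


@pytest.fixture
def toy_unit():
    """Tiny hand-built unit with known values."""
    return ExpressionUnit(
        feature_id="g1",
        cluster_id="c1",
        subject_ids=["a", "b", "c", "d"],
        values=[
            np.array([1.0, 2.0, 3.0]),
            np.array([2.0, 4.0, 6.0]),
            np.array([1.0, 1.5, 2.0]),
            np.array([5.0, 5.5, 6.0]),
        ],
        outcome=np.array([0, 0, 1, 1]),
    )


def random_density(rng, size=64):
    """Random discrete density on a shared grid (Dirichlet draw)."""
    from kernelds import DensityEstimate

    d = rng.dirichlet(np.full(size, 0.5))
    return DensityEstimate(
        grid=np.linspace(0, 1, size), density=d, bandwidth=0.01, n_cells=1
    )
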