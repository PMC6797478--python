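import numpy as np
import pytest

from gridsync.maps import ArenaSpec, RateMap, SpikeTrain, Trajectory
from gridsync.synthgen import (
    CouplingSpec,
    GridCellParams,
    InactivationSpec,
    default_grid_cohort,
    grid_rate,
    simulate_session,
    simulate_trajectory,
)


@pytest.fixture(scope="session")
def arena() -> ArenaSpec:
    return ArenaSpec(100.0)


@pytest.fixture(scope="session")
def covering_trajectory(arena) -> Trajectory:
    """Long foraging walk that visits nearly every spatial bin."""
    return simulate_trajectory(arena, duration=1200.0, seed=1)


def make_analytic_rate_map(
    arena: ArenaSpec,
    spacing: float = 35.0,
    orientation: float = 10.0,
    phase=(5.0, 5.0),
    peak_rate: float = 8.0,
    nbins: int = 50,
) -> RateMap:
    """Noise-free hexagonal rate map evaluated at bin centers."""
    bs = arena.side_length / nbins
    c = (np.arange(nbins) + 0.5) * bs
    xx, yy = np.meshgrid(c, c)
    params = GridCellParams(
        spacing=spacing, orientation=orientation, phase=phase, peak_rate=peak_rate
    )
    rate = grid_rate(params, np.column_stack([xx.ravel(), yy.ravel()]))
    return RateMap(rate.reshape(nbins, nbins), bs, arena)


@pytest.fixture(scope="session")
def hex_rate_map(arena) -> RateMap:
    return make_analytic_rate_map(arena)


@pytest.fixture(scope="session")
def coupled_session(arena):
    """One 4-cell session with shared-gain coupling and drift inactivation."""
    cells = default_grid_cohort(4, arena, seed=7)
    return simulate_session(
        cells,
        CouplingSpec(shared_gain_sd=0.5, gain_timescale=1.0),
        InactivationSpec(rate_scale=0.5, drift_sd=3.0),
        arena,
        durations={"pre": 900.0, "during": 900.0, "post": 900.0},
        seed=7,
    )


def poisson_train(
    rate_hz: float, duration: float, rng: np.random.Generator, cell_id: str = ""
) -> SpikeTrain:
    n = rng.poisson(rate_hz * duration)
    return SpikeTrain(np.sort(rng.uniform(0.0, duration, n)), 0.0, duration, cell_id)
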