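import numpy as np
import pytest

from tunnelvision import (
    AgentParams,
    PhaseSchedule,
    TrajectoryTable,
    default_two_object_layout,
    simulate_trial,
)


@pytest.fixture(scope="session")
def layout():
    return default_two_object_layout()


@pytest.fixture(scope="session")
def short_schedule():
    """Compressed three-phase trial used throughout the tests: long enough
    for activation dynamics, short enough to keep the suite quick."""
    return PhaseSchedule((("pre", 0.0, 60.0), ("co2", 60.0, 300.0), ("post", 300.0, 360.0)))


@pytest.fixture(scope="session")
def attractive_agents():
    """Cohort with a strong test-object attraction bias."""
    return AgentParams(attraction_weights={"red": 3.0, "white": 1.0})


@pytest.fixture(scope="session")
def sim_trial(layout, short_schedule, attractive_agents):
    """One simulated trial with an attractive test object, shared across
    tests that only read from it."""
    return simulate_trial(layout, short_schedule, attractive_agents, seed=42)


def make_track(
    track_id: int,
    positions: np.ndarray,
    start_frame: int = 0,
    frame_rate: float = 60.0,
) -> TrajectoryTable:
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(positions)
    return TrajectoryTable.from_records(
        np.full(n, track_id),
        start_frame + np.arange(n),
        positions,
        frame_rate=frame_rate,
    )


def stack_tables(*tables: TrajectoryTable) -> TrajectoryTable:
    import pandas as pd

    return TrajectoryTable(
        pd.concat([t.data for t in tables], ignore_index=True),
        frame_rate=tables[0].frame_rate,
    )
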