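"""Shared fixtures: synthetic fixture suite and small hand-built trajectories."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from permeon import synthetic_data as syn
from permeon.trajectory_io import IonTrajectory

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def fixtures():
    """The deterministic named fixture cases (push/pull/mixed/inward/backrun)."""
    return syn.fixture_suite(seed=FIXTURE_SEED)


def make_trajectory(rows, frame_interval=10.0, frame_range=None):
    """Trajectory from (frame, ion_id, z) tuples on a uniform grid."""
    table = pd.DataFrame(rows, columns=["frame", "ion_id", "z"])
    table.insert(1, "time_ps", table["frame"] * frame_interval)
    traj = IonTrajectory.from_table(table)
    if frame_range is not None:
        traj.frame_range = frame_range
    return traj


@pytest.fixture
def site_centers():
    """z position of the center of each site S0..S6 of the default model."""
    # default thresholds: -14, -4.5, 1.5, 4.5, 7.5, 10.5, 13.5, 18
    return {0: 15.0, 1: 12.0, 2: 9.0, 3: 6.0, 4: 3.0, 5: 0.0, 6: -9.0}


INTRA_Z = -20.0
EXTRA_Z = 25.0
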