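"""Shared fixtures.

The steady-state simulation fixtures are session-scoped because they are the
expensive part of the suite; every test that interrogates the self-organized
patterns reuses them.
"""

from __future__ import annotations

import numpy as np
import pytest

from nanocable.params import get_preset
from nanocable.render import render_positions
from nanocable.simulator import run_condition


@pytest.fixture(scope="session")
def one_m_trajectories():
    """Three steady-state runs of the isotropic, motor-free condition 1-M."""
    return [run_condition(get_preset("1-M"), {"seed": s, "duration": 90.0})
            for s in (1, 2, 3)]


@pytest.fixture(scope="session")
def four_m_trajectories():
    """Two steady-state runs of the cable-forming condition 4-M, with a fine
    early snapshot stride so the emergence ordering is resolvable."""
    return [run_condition(get_preset("4-M"), {"seed": s, "duration": 90.0},
                          snapshot_stride=0.25)
            for s in (1, 2)]


def final_frame(traj):
    return render_positions(traj.positions[-1].reshape(-1, 2))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
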