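"""Shared fixtures.

The gain-ladder fixture simulates and analyzes one full two-hour plate with
five optomotor-gain levels (two rows of 12 larvae each), once per session;
it backs the parameter-recovery, monotonicity, and exact-detection tests.
"""

from __future__ import annotations

from types import SimpleNamespace

import pytest

from plateomr import (
    DetectionConfig,
    LarvaParams,
    PeriodSchedule,
    run_detection,
    score_larvae,
    simulate_experiment,
    standard_layout,
)

GAINS = (0.0, 0.25, 0.5, 0.75, 1.0)
LADDER_SEED = 12345
LADDER_P_MOVE = 0.6


@pytest.fixture(scope="session")
def gain_ladder():
    """Full pipeline on 120 larvae: rows 2g and 2g+1 run gain GAINS[g]."""
    layout = standard_layout(1, 10, 12, pixels_per_mm=4.0)
    schedule = PeriodSchedule()
    params = {
        (0, r): LarvaParams(p_move=LADDER_P_MOVE, optomotor_gain=GAINS[r // 2])
        for r in range(10)
    }
    exp = simulate_experiment(layout, schedule, params, seed=LADDER_SEED)
    results = run_detection(exp.iter_frames(), layout, schedule, DetectionConfig())
    scores = score_larvae(results, schedule)
    scores = scores.assign(gain=[GAINS[r // 2] for r in scores["row"]])
    return SimpleNamespace(
        layout=layout,
        schedule=schedule,
        exp=exp,
        results=results,
        scores=scores,
        gains=GAINS,
        p_move=LADDER_P_MOVE,
    )
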