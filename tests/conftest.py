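from dataclasses import dataclass

import numpy as np
import pytest

from rampfix.behavior import (
    FixationInterval,
    detect_saccades,
    segment_fixations,
)
from rampfix.synthetic_data import BehaviorConfig, SRCellConfig, gen_eye_trace, gen_sr_cell


@dataclass
class Session:
    cfg: BehaviorConfig
    trace: object
    truth: object
    events: list
    fixations: list

    def truth_fixations(self) -> list[FixationInterval]:
        """Fixation intervals taken from the ground truth, not the detector."""
        labels = self.truth.direction_labels
        times = self.truth.saccade_times_s
        return [
            FixationInterval(times[k], times[k + 1], labels[k], labels[k + 1])
            for k in range(len(times) - 1)
        ]


@pytest.fixture(scope="session")
def session() -> Session:
    """A moderate noise-free behavior session with detected events."""
    cfg = BehaviorConfig(duration_s=2000.0, seed=3)
    trace, truth = gen_eye_trace(cfg)
    events = detect_saccades(trace)
    fixations = segment_fixations(events, trace)
    return Session(cfg, trace, truth, events, fixations)


@pytest.fixture(scope="session")
def sr_cells(session) -> list:
    """Eight low-noise SR cells, alternating preferred directions."""
    cells = []
    for i in range(8):
        cfg = SRCellConfig(
            preferred_direction="L" if i % 2 == 0 else "R",
            noise_sd=0.02,
            slope_noise_cv=0.05,
            seed=10 + i,
        )
        cells.append(gen_sr_cell(cfg, session.truth, cell_id=f"sr{i}"))
    return cells
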