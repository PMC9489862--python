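import numpy as np
import pandas as pd
import pytest

from barrelpop.session import AnalysisWindow, Session, make_trial_table
from barrelpop.synth import SimConfig, generate_session


def tiny_config(**kw):
    """Small, fast session config used across the unit tests."""
    defaults = dict(n_cells=12, n_trials=24, stage="expert",
                    time_cell_fraction=0.0, image_size=96,
                    trial_period_s=8.0)
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_session():
    cfg = tiny_config()
    return generate_session(cfg, seed=123)


@pytest.fixture()
def manual_session():
    """Hand-built 2-cell session with fully controlled trials and licks."""
    rng = np.random.default_rng(0)
    n_frames = 3000
    traces = 100.0 + rng.normal(0, 1.0, (2, n_frames))
    trials = make_trial_table(
        start_frames=[300, 600, 900, 1200],
        stimulus_present=[True, False, True, False])
    masks = [np.zeros((32, 32), dtype=bool) for _ in range(2)]
    for i, m in enumerate(masks):
        m[5 + 10 * i:9 + 10 * i, 5:9] = True
    return Session(traces=traces, roi_masks=masks,
                   mean_image=rng.random((32, 32)), trials=trials,
                   lick_times=np.array([10.5, 11.0, 31.0]),
                   frame_rate=30.0)


@pytest.fixture()
def window():
    return AnalysisWindow()
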