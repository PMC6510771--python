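import numpy as np
import pandas as pd
import pytest

import watermaze as wm

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture
def arena():
    """Test arena: 160 cm pool centred at the origin, platform north at (0, 50)."""
    return wm.ArenaConfig(platform_center=wm.Point(0.0, 50.0))


def make_trajectory(points, dt=0.2, **kwargs):
    """Build a trajectory from a point list sampled every ``dt`` seconds."""
    points = np.asarray(points, dtype=float)
    t = np.arange(len(points)) * dt
    return wm.Trajectory(t=t, xy=points, record_frequency=1.0 / dt, **kwargs)


@pytest.fixture(scope="session")
def study_indices():
    """Indices table of the full default simulated study (19 + 20 x 20 trainings)."""
    cfg = wm.ScenarioConfig(seed=7)
    records = wm.simulate_study(cfg)
    rows = []
    for rec in records:
        res = wm.compute_indices(rec.trajectory, cfg.arena)
        row = res.as_dict()
        row["group"] = rec.group
        row["training"] = rec.training
        rows.append(row)
    return pd.DataFrame(rows)
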