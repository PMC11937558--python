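"""Shared fixtures: small simulated herds reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from equiprox import EnclosureConfig, SimConfig, clean_all, simulate_herd, trajectories_to_distances
from equiprox.simulate import NoiseConfig, schedule_events


def series_df(d, t0=0):
    """Distance series DataFrame at 1 Hz from a list of cm values."""
    d = np.asarray(d, dtype=float)
    return pd.DataFrame({"t": t0 + np.arange(len(d), dtype=np.int64), "d": d})


@pytest.fixture(scope="session")
def paddock_enclosure():
    return EnclosureConfig(length_m=30, width_m=15, n_horses=8, tracking_hours=1.0)


@pytest.fixture(scope="session")
def scripted_sim():
    """Noise-free 8-agent paddock with 20 scripted agonistic episodes."""
    ids = [f"h{i + 1:02d}" for i in range(8)]
    sched = schedule_events(20, 1400, ids, seed=40)
    cfg = SimConfig(
        enclosure_length_m=30,
        enclosure_width_m=15,
        n_agents=8,
        duration_s=1400,
        seed=33,
        event_schedule=sched,
        noise=NoiseConfig.off(),
    )
    sim = simulate_herd(cfg)
    table = trajectories_to_distances(sim, seed=34)
    return sim, table


@pytest.fixture(scope="session")
def scripted_series(scripted_sim, paddock_enclosure):
    sim, table = scripted_sim
    series, _ = clean_all(table, sim.config.agent_ids, paddock_enclosure)
    return sim, series
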