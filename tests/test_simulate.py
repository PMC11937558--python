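"""Herd simulator: force-model convergence, determinism, sensor model and
ground-truth bookkeeping."""

import numpy as np
import pytest

from equiprox import (
    GroundTruth,
    ScriptedEvent,
    SimConfig,
    SimResult,
    simulate_herd,
    trajectories_to_distances,
)
from equiprox.simulate import EPOCH0, NoiseConfig, schedule_events


def _pair_distance(sim):
    return np.hypot(*(sim.positions[:, 0] - sim.positions[:, 1]).T)


class TestForceModel:
    def test_two_agents_converge_to_equilibrium_band(self):
        cfg = SimConfig(
            30, 30, 2, 2000, seed=5,
            affinity=np.array([[0.0, 1.0], [1.0, 0.0]]),
            equilibrium_dist_m=3.0, noise=NoiseConfig.off(),
        )
        d = _pair_distance(simulate_herd(cfg))
        assert 2.4 <= d[200:].mean() <= 3.6  # ±20% of the 3 m equilibrium

    def test_deterministic_limit_reaches_exact_equilibrium(self):
        cfg = SimConfig(
            30, 30, 2, 600, seed=5,
            affinity=np.array([[0.0, 1.0], [1.0, 0.0]]),
            equilibrium_dist_m=3.0, wander_sd_m_s=0.0, noise=NoiseConfig.off(),
        )
        d = _pair_distance(simulate_herd(cfg))
        assert d[-1] == pytest.approx(3.0, abs=1e-6)

    def test_positions_stay_inside_enclosure(self):
        cfg = SimConfig(20, 10, 6, 900, seed=2)
        pos = simulate_herd(cfg).positions
        assert pos[..., 0].min() >= 0 and pos[..., 0].max() <= 20
        assert pos[..., 1].min() >= 0 and pos[..., 1].max() <= 10

    def test_enclosure_size_monotonicity(self):
        """Identical roster/affinity: the herd spreads out more in a field
        than in a paddock."""
        from equiprox import default_affinity

        aff = default_affinity(8, 42)
        med = {}
        for name, (L, W) in {"paddock": (30, 15), "field": (65, 40)}.items():
            cfg = SimConfig(L, W, 8, 3600, seed=9, affinity=aff, noise=NoiseConfig.off())
            sim = simulate_herd(cfg)
            dists = [
                np.median(np.hypot(*(sim.positions[:, i] - sim.positions[:, j]).T))
                for i in range(8) for j in range(i + 1, 8)
            ]
            med[name] = np.median(dists)
        assert med["field"] > med["paddock"]


class TestDeterminismAndGroundTruth:
    def test_identical_seed_bitwise_identical(self):
        a = simulate_herd(SimConfig(30, 15, 6, 600, seed=9))
        b = simulate_herd(SimConfig(30, 15, 6, 600, seed=9))
        assert np.array_equal(a.positions, b.positions)
        ta = trajectories_to_distances(a, seed=10)
        tb = trajectories_to_distances(b, seed=10)
        assert ta.equals(tb)

    def test_no_scripted_events_empty_ground_truth(self):
        sim = simulate_herd(SimConfig(30, 15, 4, 600, seed=1))
        assert sim.ground_truth.events == []

    def test_every_scripted_event_logged_once(self):
        ids = [f"h{i + 1:02d}" for i in range(6)]
        sched = schedule_events(8, 900, ids, seed=3)
        cfg = SimConfig(30, 15, 6, 900, seed=4, event_schedule=sched, noise=NoiseConfig.off())
        sim = simulate_herd(cfg)
        assert len(sim.ground_truth.events) == 8

    def test_event_validation(self):
        with pytest.raises(ValueError):
            ScriptedEvent(t_start_s=0, aggressor="a", target="a")
        with pytest.raises(ValueError):
            ScriptedEvent(t_start_s=0, aggressor="a", target="b", approach_speed_cm_s=50)
        ev = ScriptedEvent(t_start_s=100, aggressor="h01", target="zz")
        with pytest.raises(ValueError):
            SimConfig(30, 15, 4, 600, seed=0, event_schedule=[ev])


def _static_sim(positions_m, n_agents, L=30.0, W=30.0, noise=None):
    """SimResult with externally fixed trajectories (no dynamics)."""
    T = positions_m.shape[0]
    ids = [f"h{i + 1:02d}" for i in range(n_agents)]
    cfg = SimConfig(L, W, n_agents, max(T, 60), seed=0, noise=noise or NoiseConfig.off())
    gt = GroundTruth(
        times=EPOCH0 + np.arange(T, dtype=np.int64),
        positions=positions_m,
        agent_ids=ids,
    )
    return SimResult(config=cfg, ground_truth=gt)


class TestSensorModel:
    def test_stationary_pair_constant_channels(self):
        pos = np.zeros((120, 2, 2))
        pos[:, 1, 0] = 10.0  # 10 m apart
        sim = _static_sim(pos, 2)
        tab = trajectories_to_distances(sim, noise=NoiseConfig.off(), seed=0)
        ab = tab[(tab.sensor_a == "h01") & (tab.sensor_b == "h02")]["distance_cm"]
        ba = tab[(tab.sensor_a == "h02") & (tab.sensor_b == "h01")]["distance_cm"]
        assert (ab == 1000.0).all() and (ba == 1000.0).all()

    def test_replicate_noise_channel_difference_sd(self):
        pos = np.zeros((4000, 2, 2))
        pos[:, 1, 0] = 10.0
        sim = _static_sim(pos, 2)
        noise = NoiseConfig(jitter_sd_cm=0, replicate_sd_cm=5, p_spike=0, p_under5=0)
        tab = trajectories_to_distances(sim, noise=noise, seed=1)
        ab = tab[(tab.sensor_a == "h01") & (tab.sensor_b == "h02")]["distance_cm"].to_numpy()
        ba = tab[(tab.sensor_a == "h02") & (tab.sensor_b == "h01")]["distance_cm"].to_numpy()
        assert np.std(ab - ba) == pytest.approx(np.sqrt(2) * 5, rel=0.1)

    def test_common_mode_jitter_cancels_in_difference(self):
        pos = np.zeros((2000, 2, 2))
        pos[:, 1, 0] = 10.0
        sim = _static_sim(pos, 2)
        noise = NoiseConfig(jitter_sd_cm=8, replicate_sd_cm=0, p_spike=0, p_under5=0)
        tab = trajectories_to_distances(sim, noise=noise, seed=2)
        ab = tab[(tab.sensor_a == "h01") & (tab.sensor_b == "h02")]["distance_cm"].to_numpy()
        ba = tab[(tab.sensor_a == "h02") & (tab.sensor_b == "h01")]["distance_cm"].to_numpy()
        assert np.allclose(ab, ba)
        assert np.std(ab) == pytest.approx(8, rel=0.15)

    def test_frozen_segment_logged_once_with_length(self):
        pos = np.zeros((120, 2, 2))
        pos[:, 1, 0] = 10.0
        noise = NoiseConfig(
            jitter_sd_cm=1, replicate_sd_cm=1, p_spike=0, p_under5=0,
            frozen_segments=[(("h01", "h02"), 30, 12)],
        )
        sim = _static_sim(pos, 2, noise=noise)
        tab = trajectories_to_distances(sim, seed=3)
        frozen = [a for a in sim.ground_truth.injected_artifacts if a["class"] == "frozen"]
        assert len(frozen) == 1 and frozen[0]["length"] == 12
        ab = tab[(tab.sensor_a == "h01") & (tab.sensor_b == "h02")]["distance_cm"].to_numpy()
        assert len(set(ab[30:42])) == 1  # held at the segment's first value

    def test_artifact_probabilities_validated(self):
        with pytest.raises(ValueError):
            NoiseConfig(p_spike=1.5)
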