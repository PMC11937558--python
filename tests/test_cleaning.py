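"""Cleaning chain: range / frozen / feeder filters, replicate averaging."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from equiprox import (
    EnclosureConfig,
    average_replicates,
    clean_dyad,
    filter_feeder,
    filter_frozen,
    filter_range,
    load_distance_csv,
)
from .conftest import series_df

ENC = EnclosureConfig(length_m=30, width_m=15, n_horses=8)


class TestLoader:
    def test_valid_rows_parsed(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "timestamp,sensor_a,sensor_b,distance_cm\n"
            "2025-01-01T00:00:00Z,a,b,100\n"
            "2025-01-01T00:00:01Z,a,b,110\n"
            "2025-01-01T00:00:02Z,a,b,120\n"
        )
        table, rep = load_distance_csv(p, ["a", "b"])
        assert len(table) == 3 and rep["unknown_id"] == 0
        assert table["t"].tolist() == [1735689600, 1735689601, 1735689602]

    def test_unknown_id_rejected_and_counted(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "timestamp,sensor_a,sensor_b,distance_cm\n0,a,b,100\n1,a,b,110\n2,zz,b,120\n"
        )
        table, rep = load_distance_csv(p, ["a", "b"])
        assert len(table) == 2 and rep["unknown_id"] == 1

    def test_duplicate_timestamps_collapsed_by_mean_and_sorted(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "timestamp,sensor_a,sensor_b,distance_cm\n5,a,b,300\n3,a,b,100\n3,a,b,200\n"
        )
        table, _ = load_distance_csv(p, ["a", "b"])
        assert table["t"].tolist() == [3, 5]
        assert table["distance_cm"].tolist() == [150.0, 300.0]

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("timestamp,sensor_a,sensor_b,distance_cm\n")
        with pytest.raises(ValueError):
            load_distance_csv(p, ["a"])


class TestRangeFilter:
    @pytest.mark.parametrize(
        "value, kept",
        [(3400.0, False), (3.0, False), (1000.0, True), (5.0, True), (4.9, False)],
    )
    def test_physical_range(self, value, kept):
        # 30 x 15 m enclosure diagonal ≈ 3354 cm
        out, removed = filter_range(series_df([value]), ENC)
        assert (len(out) == 1) is kept
        assert removed == (0 if kept else 1)


class TestFrozenFilter:
    @pytest.mark.parametrize("run_len, kept", [(12, 0), (11, 0), (10, 10)])
    def test_identical_runs(self, run_len, kept):
        out, removed = filter_frozen(series_df([500.0] * run_len))
        assert len(out) == kept and removed == run_len - kept

    def test_alternating_values_retained(self):
        d = [500.0, 501.0] * 10
        out, removed = filter_frozen(series_df(d))
        assert removed == 0 and len(out) == 20

    def test_run_removed_in_full_with_neighbours_kept(self):
        d = [100.0] + [200.0] * 12 + [300.0]
        out, removed = filter_frozen(series_df(d))
        assert removed == 12 and out["d"].tolist() == [100.0, 300.0]


class TestFeederFilter:
    def test_both_near_removed_one_near_retained(self):
        s = series_df([500.0, 600.0])
        fa = series_df([250.0, 250.0])
        fb = series_df([280.0, 900.0])
        out, removed = filter_feeder(s, fa, fb)
        assert removed == 1 and out["d"].tolist() == [600.0]

    def test_missing_feeder_channel_warns_and_passes_through(self):
        s = series_df([500.0, 600.0])
        with pytest.warns(UserWarning):
            out, removed = filter_feeder(s, None, None)
        assert removed == 0 and len(out) == 2

    def test_nearest_sample_within_one_second(self):
        s = series_df([500.0], t0=10)
        fa = series_df([100.0], t0=11)  # 1 s offset still matches
        fb = series_df([100.0], t0=11)
        out, removed = filter_feeder(s, fa, fb)
        assert removed == 1


class TestReplicateAveraging:
    def test_mean_of_both_channels(self):
        out = average_replicates(series_df([100.0]), series_df([110.0]))
        assert out["d"].tolist() == [105.0]

    def test_single_sided_retention(self):
        ab = series_df([100.0, 200.0])
        ba = series_df([110.0])  # missing at t=1
        out = average_replicates(ab, ba)
        assert out["d"].tolist() == [105.0, 200.0]

    def test_no_samples_no_rows(self):
        out = average_replicates(series_df([]), series_df([]))
        assert len(out) == 0


@settings(max_examples=40, deadline=None)
@given(
    st.lists(st.floats(min_value=1.0, max_value=4000.0, allow_nan=False), min_size=1, max_size=60)
)
def test_filters_are_idempotent(values):
    s = series_df(values)
    once_r, n1 = filter_range(s, ENC)
    twice_r, n2 = filter_range(once_r, ENC)
    assert n2 == 0 and twice_r["d"].tolist() == once_r["d"].tolist()
    once_f, _ = filter_frozen(s)
    twice_f, m2 = filter_frozen(once_f)
    assert m2 == 0 and twice_f["d"].tolist() == once_f["d"].tolist()


def test_clean_dyad_provenance_accounts_for_every_sample(scripted_sim, paddock_enclosure):
    sim, table = scripted_sim
    ds = clean_dyad(table, "h01", "h02", paddock_enclosure)
    p = ds.provenance
    assert p["raw"] == p["kept_channel_samples"] + p["range"] + p["frozen"] + p["feeder"]
    assert np.all(np.diff(ds.t) > 0)
    assert np.all(ds.d >= 5.0)


def test_filters_remove_injected_artifacts_only(paddock_enclosure):
    """Range + frozen filters catch every injected artifact sample and no
    clean sample, on a simulated herd with known artifact positions."""
    from equiprox import SimConfig, simulate_herd, trajectories_to_distances
    from equiprox.cleaning import _channel
    from equiprox.simulate import NoiseConfig

    noise = NoiseConfig(
        jitter_sd_cm=2.0,
        replicate_sd_cm=3.0,
        p_spike=0.003,
        p_under5=0.002,
        frozen_segments=[(("h01", "h02"), 50, 12), (("h03", "h04"), 200, 20)],
    )
    cfg = SimConfig(30, 15, 6, 600, seed=21, noise=noise)
    sim = simulate_herd(cfg)
    table = trajectories_to_distances(sim, seed=22)
    gt = sim.ground_truth
    bad = {
        (a["sensor_a"], a["sensor_b"], a["t"])
        for a in gt.injected_artifacts
        if a["class"] in ("spike", "under5")
    }
    for a in gt.injected_artifacts:
        if a["class"] == "frozen":
            for dt in range(a["length"]):
                bad.add((a["sensor_a"], a["sensor_b"], a["t"] + dt))
                bad.add((a["sensor_b"], a["sensor_a"], a["t"] + dt))
    assert len(bad) > 50
    surviving_bad = wrongly_removed = 0
    ids = cfg.agent_ids
    for i, a in enumerate(ids):
        for b in ids:
            if a == b:
                continue
            ch = _channel(table, a, b)
            keys = list(zip([a] * len(ch), [b] * len(ch), ch["t"].astype(int)))
            ch1, _ = filter_range(ch, paddock_enclosure)
            ch2, _ = filter_frozen(ch1)
            kept = set(zip([a] * len(ch2), [b] * len(ch2), ch2["t"].astype(int)))
            for k in keys:
                if k in bad and k in kept:
                    surviving_bad += 1
                if k not in bad and k not in kept:
                    wrongly_removed += 1
    assert surviving_bad == 0
    assert wrongly_removed == 0
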