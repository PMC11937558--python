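"""Rule-based detection of agonistic approaches and retreats.

An agonistic approach is a window of at most 3 s of consecutive 1 Hz samples
in which the dyadic distance drops by ≥100 cm to below 200 cm, the
window-mean closing speed is ≥85 cm/s, and the distance is monotonically
decreasing within a 1 cm jitter tolerance ("consistent direction"). A
retreat is a ≥100 cm rise within ≤3 s beginning within 3 s after an
approach; it is high-intensity if its mean speed is ≥85 cm/s, otherwise
low-intensity (a fast retreat is never double-counted as low).

Instantaneous speeds are signed per-step distance changes over the actual
sampling interval; magnitudes above 800 cm/s are physically impossible and
flag the later sample as a measurement error, excluding it from all event
windows. Event windows additionally require unit (1 s) steps, so no event
spans a cleaning gap.

Overlapping qualifying windows of one dyad merge into a single event
(earliest start, latest end). Candidate approaches of different dyads that
share an animal and overlap in time void each other — the published
definition admits only two animals per event.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .cleaning import DistanceSeries
from .config import EventConfig

EVENT_COLUMNS = [
    "event_id", "kind", "animal_a", "animal_b",
    "t_start", "t_end", "displacement_cm", "mean_speed_cm_s", "linked_id",
]


def compute_speeds(series: pd.DataFrame, max_speed_cm_s: float = 800.0) -> pd.DataFrame:
    """Signed per-step speed v = Δd/Δt (cm/s) over the actual interval.

    The first sample has no speed (NaN). A sample whose incoming speed
    exceeds ``max_speed_cm_s`` in magnitude is flagged as a measurement
    error and excluded from event logic.
    """
    t = series["t"].to_numpy(dtype=float)
    d = series["d"].to_numpy(dtype=float)
    v = np.full(len(d), np.nan)
    if len(d) > 1:
        v[1:] = np.diff(d) / np.diff(t)
    flagged = np.abs(v) > max_speed_cm_s
    flagged[np.isnan(v)] = False
    return pd.DataFrame({"t": series["t"].to_numpy(), "d": d, "v": v, "flagged": flagged})


def _qualifying_windows(
    t: np.ndarray,
    d: np.ndarray,
    flagged: np.ndarray,
    cfg: EventConfig,
    direction: str,
) -> list[tuple[int, int]]:
    """(t_start, t_end) of all windows satisfying the approach (or rise)
    criteria. ``direction`` is "approach" (drop, end-distance and speed-floor
    checks) or "retreat" (rise only; speed classifies later)."""
    n = len(t)
    out: list[tuple[int, int]] = []
    if n < 2:
        return out
    eps = 1e-6  # cm-scale float tolerance: a drop of exactly 100 cm qualifies
    flag_cum = np.concatenate([[0], np.cumsum(flagged)])
    step = np.diff(d)
    for L in range(1, cfg.window_s + 1):
        if n <= L:
            break
        i = np.arange(n - L)
        unit_steps = (t[i + L] - t[i]) == L
        clean = (flag_cum[i + L + 1] - flag_cum[i + 1]) == 0
        ok = unit_steps & clean
        if direction == "approach":
            drop = d[i] - d[i + L]
            ok &= drop >= cfg.min_drop_cm - eps
            ok &= d[i + L] < cfg.end_below_cm
            if cfg.speed_floor_mode == "window":
                ok &= drop / L >= cfg.min_speed_cm_s - eps
            # monotone decrease within jitter tolerance
            mono = np.ones(n - L, dtype=bool)
            for k in range(L):
                s = step[i + k]
                mono &= s <= cfg.jitter_tol_cm + eps
                if cfg.speed_floor_mode == "step":
                    mono &= -s >= cfg.min_speed_cm_s - eps
            ok &= mono
        else:
            rise = d[i + L] - d[i]
            ok &= rise >= cfg.min_drop_cm - eps
            mono = np.ones(n - L, dtype=bool)
            for k in range(L):
                mono &= step[i + k] >= -cfg.jitter_tol_cm - eps
            ok &= mono
        for start in np.nonzero(ok)[0]:
            out.append((int(t[start]), int(t[start + L])))
    out.sort()
    return out


def _merge_windows(windows: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge windows that overlap or share an endpoint sample."""
    merged: list[list[int]] = []
    for s, e in windows:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def detect_approaches(
    series_by_dyad: Mapping[tuple[str, str], DistanceSeries],
    cfg: Optional[EventConfig] = None,
) -> pd.DataFrame:
    """Agonistic approach events across all dyads of a group."""
    cfg = cfg or EventConfig()
    candidates = []
    for dyad, ds in sorted(series_by_dyad.items()):
        sp = compute_speeds(ds.samples, max_speed_cm_s=cfg.max_speed_cm_s)
        t, d, fl = sp["t"].to_numpy(), sp["d"].to_numpy(), sp["flagged"].to_numpy()
        windows = _qualifying_windows(t, d, fl, cfg, "approach")
        t_index = {int(tt): k for k, tt in enumerate(t)}
        for s, e in _merge_windows(windows):
            disp = d[t_index[e]] - d[t_index[s]]
            candidates.append(
                {
                    "kind": "approach",
                    "animal_a": dyad[0],
                    "animal_b": dyad[1],
                    "t_start": s,
                    "t_end": e,
                    "displacement_cm": float(disp),
                    "mean_speed_cm_s": float(abs(disp) / (e - s)),
                }
            )

    # criterion: only two animals per event — concurrent candidates sharing
    # an animal void each other
    discard = set()
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            ci, cj = candidates[i], candidates[j]
            share = {ci["animal_a"], ci["animal_b"]} & {cj["animal_a"], cj["animal_b"]}
            same_dyad = {ci["animal_a"], ci["animal_b"]} == {cj["animal_a"], cj["animal_b"]}
            if share and not same_dyad:
                if ci["t_start"] <= cj["t_end"] and cj["t_start"] <= ci["t_end"]:
                    discard.update((i, j))
    kept = [c for k, c in enumerate(candidates) if k not in discard]
    kept.sort(key=lambda c: (c["t_start"], c["animal_a"], c["animal_b"]))
    for eid, c in enumerate(kept):
        c["event_id"] = eid
        c["linked_id"] = pd.NA
    return pd.DataFrame(kept, columns=EVENT_COLUMNS)


def detect_retreats(
    approaches: pd.DataFrame,
    series_by_dyad: Mapping[tuple[str, str], DistanceSeries],
    cfg: Optional[EventConfig] = None,
) -> pd.DataFrame:
    """High- and low-intensity retreats linked to detected approaches.

    For each approach the first cluster of qualifying rise windows starting
    within ``retreat_lag_s`` after the approach end is taken; its merged
    mean speed classifies the retreat (≥ speed floor ⇒ high intensity). At
    most one retreat is linked per approach.
    """
    cfg = cfg or EventConfig()
    rows = []
    eid = int(approaches["event_id"].max()) + 1 if len(approaches) else 0
    speeds_cache: dict[tuple[str, str], pd.DataFrame] = {}
    for ap in approaches.itertuples():
        dyad = (ap.animal_a, ap.animal_b)
        if dyad not in speeds_cache:
            speeds_cache[dyad] = compute_speeds(
                series_by_dyad[dyad].samples, max_speed_cm_s=cfg.max_speed_cm_s
            )
        sp = speeds_cache[dyad]
        t, d, fl = sp["t"].to_numpy(), sp["d"].to_numpy(), sp["flagged"].to_numpy()
        windows = [
            (s, e)
            for s, e in _qualifying_windows(t, d, fl, cfg, "retreat")
            if ap.t_end <= s <= ap.t_end + cfg.retreat_lag_s
        ]
        if not windows:
            continue
        s, e = _merge_windows(windows)[0]
        t_index = {int(tt): k for k, tt in enumerate(t)}
        disp = float(d[t_index[e]] - d[t_index[s]])
        speed = abs(disp) / (e - s)
        # classify by the earliest qualifying window: ordinary herd motion
        # merged onto the tail of the flight must not re-grade its intensity
        ws, we = windows[0]
        class_speed = (d[t_index[we]] - d[t_index[ws]]) / (we - ws)
        rows.append(
            {
                "event_id": eid,
                "kind": "high_retreat" if class_speed >= cfg.min_speed_cm_s else "low_retreat",
                "animal_a": ap.animal_a,
                "animal_b": ap.animal_b,
                "t_start": s,
                "t_end": e,
                "displacement_cm": disp,
                "mean_speed_cm_s": float(speed),
                "linked_id": ap.event_id,
            }
        )
        eid += 1
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def detect_events(
    series_by_dyad: Mapping[tuple[str, str], DistanceSeries],
    cfg: Optional[EventConfig] = None,
) -> pd.DataFrame:
    """Approaches plus linked retreats, as one event log."""
    cfg = cfg or EventConfig()
    approaches = detect_approaches(series_by_dyad, cfg)
    retreats = detect_retreats(approaches, series_by_dyad, cfg)
    return pd.concat([approaches, retreats], ignore_index=True)


def event_rate(n_events: int, n_horses: int, tracking_hours: float) -> float:
    """Events per animal-hour: n / (animals × hours). With ``n_horses=1``
    this is the pooled per-group-hour rate."""
    if tracking_hours <= 0:
        raise ValueError("tracking_hours must be positive")
    if n_horses < 1:
        raise ValueError("n_horses must be >= 1")
    return n_events / (n_horses * tracking_hours)


def cm_s_to_km_h(v: float) -> float:
    """cm/s → km/h (× 0.036)."""
    return v * 0.036


def summarize_rates(
    events: pd.DataFrame, n_horses: int, tracking_hours: float, condition: str
) -> pd.DataFrame:
    """Per-kind count, per-animal-hour and per-group-hour rates, and median
    speed in cm/s and km/h (reported to 2 decimals, half-up)."""
    rows = []
    for kind in ("approach", "high_retreat", "low_retreat"):
        sub = events[events["kind"] == kind]
        med_speed = float(sub["mean_speed_cm_s"].median()) if len(sub) else float("nan")
        rows.append(
            {
                "condition": condition,
                "kind": kind,
                "n_events": int(len(sub)),
                "rate_per_horse_hour": round_half_up(
                    event_rate(len(sub), n_horses, tracking_hours), 2
                ),
                "rate_per_group_hour": round_half_up(event_rate(len(sub), 1, tracking_hours), 2),
                "median_speed_cm_s": med_speed,
                "median_speed_km_h": round_half_up(cm_s_to_km_h(med_speed), 2)
                if len(sub)
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def score_events(
    detected: pd.DataFrame,
    truth_events: Sequence,
    tol_s: int = 3,
) -> dict:
    """Precision/recall of detected events against simulator ground truth.

    A detected event matches a ground-truth episode leg if it involves the
    same unordered dyad, has the same kind, and its window overlaps the true
    window padded by ``tol_s``. Matching is greedy one-to-one in time order.
    """
    out = {}
    truth_by_kind = {
        "approach": [(e.dyad, e.approach_t0, e.approach_t1) for e in truth_events],
        "high_retreat": [
            (e.dyad, e.retreat_t0, e.retreat_t1) for e in truth_events if e.retreat_kind == "high_retreat"
        ],
        "low_retreat": [
            (e.dyad, e.retreat_t0, e.retreat_t1) for e in truth_events if e.retreat_kind == "low_retreat"
        ],
    }
    for kind, truths in truth_by_kind.items():
        det = detected[detected["kind"] == kind].sort_values("t_start")
        used = set()
        matched = 0
        for row in det.itertuples():
            dy = tuple(sorted((row.animal_a, row.animal_b)))
            for k, (tdy, t0, t1) in enumerate(truths):
                if k in used or tdy != dy:
                    continue
                if row.t_start <= t1 + tol_s and t0 - tol_s <= row.t_end:
                    used.add(k)
                    matched += 1
                    break
        n_det, n_true = len(det), len(truths)
        out[kind] = {
            "n_detected": n_det,
            "n_true": n_true,
            "precision": matched / n_det if n_det else float("nan"),
            "recall": matched / n_true if n_true else float("nan"),
        }
    return out
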