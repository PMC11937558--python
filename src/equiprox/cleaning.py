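"""Ingest raw dyadic distance streams and apply the four cleaning rules.

Cleaning order: range filter → frozen-run filter → feeder filter →
technical-replicate averaging. Frozen-run detection operates on the raw
directed channels before averaging, since a frozen reading is a failure of
one sensor pair. "No variation" means bit-identical cm values (tolerance 0):
genuine UWB readings are inherently variable, so exact constancy over more
than 10 consecutive seconds marks a stuck channel. Gaps are left as gaps —
no interpolation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from ._util import dyad_key
from .config import EnclosureConfig, FilterConfig

logger = logging.getLogger(__name__)

RAW_COLUMNS = ["timestamp", "sensor_a", "sensor_b", "distance_cm"]


@dataclass
class DistanceSeries:
    """Canonical cleaned 1 Hz series for one unordered dyad.

    ``samples`` has strictly increasing epoch-second column ``t`` and
    distance column ``d`` (cm). ``provenance`` counts raw samples removed by
    each filter across both directed channels.
    """

    dyad: tuple[str, str]
    samples: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def t(self) -> np.ndarray:
        return self.samples["t"].to_numpy()

    @property
    def d(self) -> np.ndarray:
        return self.samples["d"].to_numpy()

    def __len__(self) -> int:
        return len(self.samples)


def load_distance_csv(path, roster: Iterable[str]) -> tuple[pd.DataFrame, dict]:
    """Parse a long-format distance CSV into (table, load report).

    Timestamps may be ISO-8601 or integer epoch seconds. Rows whose sensor
    ids are outside the roster, or that fail to parse, are dropped and
    counted. Within each directed channel, duplicate timestamps are
    collapsed by their mean and rows sorted by time.
    """
    raw = pd.read_csv(path, dtype={"sensor_a": str, "sensor_b": str})
    missing = [c for c in RAW_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"missing columns {missing} in {path}")
    if raw.empty:
        raise ValueError(f"no data rows in {path}")

    n_raw = len(raw)
    ts = pd.to_numeric(raw["timestamp"], errors="coerce")
    t = ts.astype(float)
    if ts.isna().any():
        iso = pd.to_datetime(
            raw.loc[ts.isna(), "timestamp"], errors="coerce", utc=True, format="ISO8601"
        )
        t.loc[ts.isna()] = (iso - pd.Timestamp(0, tz="UTC")) // pd.Timedelta("1s")
    d = pd.to_numeric(raw["distance_cm"], errors="coerce")
    ok = t.notna() & d.notna()
    n_malformed = int((~ok).sum())

    roster = set(roster)
    table = pd.DataFrame(
        {
            "t": t[ok].astype(np.int64),
            "sensor_a": raw.loc[ok, "sensor_a"],
            "sensor_b": raw.loc[ok, "sensor_b"],
            "distance_cm": d[ok].astype(float),
        }
    )
    in_roster = table["sensor_a"].isin(roster) & (
        table["sensor_b"].isin(roster) | (table["sensor_b"] == "feeder")
    )
    n_unknown = int((~in_roster).sum())
    table = table[in_roster]

    # collapse duplicate timestamps within a directed channel by their mean
    table = (
        table.groupby(["sensor_a", "sensor_b", "t"], as_index=False)["distance_cm"]
        .mean()
        .sort_values(["sensor_a", "sensor_b", "t"], kind="mergesort")
        .reset_index(drop=True)
    )
    report = {"rows_read": n_raw, "malformed": n_malformed, "unknown_id": n_unknown}
    if n_malformed or n_unknown:
        logger.info("load_distance_csv: dropped %d malformed, %d unknown-id rows", n_malformed, n_unknown)
    return table, report


def filter_range(
    series: pd.DataFrame, enclosure: EnclosureConfig, min_cm: float = 5.0
) -> tuple[pd.DataFrame, int]:
    """Drop physically impossible readings: above the enclosure diagonal or
    below the sensor-placement minimum (strictly less than ``min_cm``)."""
    d = series["d"]
    keep = (d >= min_cm) & (d <= enclosure.max_theoretical_cm)
    return series[keep].reset_index(drop=True), int((~keep).sum())


def filter_frozen(series: pd.DataFrame, window_s: int = 10) -> tuple[pd.DataFrame, int]:
    """Remove, in full, every maximal run of identical consecutive values
    lasting more than ``window_s`` seconds (strictly greater: a run of
    exactly 10 identical 1 Hz samples survives)."""
    if len(series) == 0:
        return series, 0
    d = series["d"].to_numpy()
    new_run = np.ones(len(d), dtype=bool)
    new_run[1:] = d[1:] != d[:-1]
    run_id = np.cumsum(new_run)
    run_len = np.bincount(run_id)[run_id]
    keep = run_len <= window_s
    return series[keep].reset_index(drop=True), int((~keep).sum())


def filter_feeder(
    series: pd.DataFrame,
    feeder_series_a: Optional[pd.DataFrame],
    feeder_series_b: Optional[pd.DataFrame],
    radius_cm: float = 300.0,
) -> tuple[pd.DataFrame, int]:
    """Drop samples where *both* animals are concurrently within the feeder
    radius; samples with only one animal near the feeder are retained.

    Feeder proximity is taken from each animal's feeder channel at the
    nearest sample within ±1 s. Without a feeder channel this is a no-op
    (with a warning), since forced co-proximity cannot be assessed.
    """
    if feeder_series_a is None or feeder_series_b is None or len(series) == 0:
        if feeder_series_a is None or feeder_series_b is None:
            warnings.warn("no feeder channel available; feeder filter skipped", stacklevel=2)
        return series, 0

    def nearest(feeder: pd.DataFrame) -> pd.Series:
        f = feeder.sort_values("t")
        merged = pd.merge_asof(
            series[["t"]].astype({"t": np.int64}),
            f.rename(columns={"d": "fd"}).astype({"t": np.int64}),
            on="t",
            direction="nearest",
            tolerance=1,
        )
        return merged["fd"]

    fa, fb = nearest(feeder_series_a), nearest(feeder_series_b)
    both_near = (fa <= radius_cm) & (fb <= radius_cm)
    both_near = both_near.fillna(False).to_numpy()
    return series[~both_near].reset_index(drop=True), int(both_near.sum())


def average_replicates(channel_ab: pd.DataFrame, channel_ba: pd.DataFrame) -> pd.DataFrame:
    """Average the two directed channels per timestamp; a timestamp present
    in only one channel keeps that channel's value."""
    merged = pd.merge(
        channel_ab.rename(columns={"d": "d_ab"}),
        channel_ba.rename(columns={"d": "d_ba"}),
        on="t",
        how="outer",
        sort=True,
    )
    merged["d"] = merged[["d_ab", "d_ba"]].mean(axis=1)
    return merged[["t", "d"]].reset_index(drop=True)


def _channel(table: pd.DataFrame, a: str, b: str) -> pd.DataFrame:
    sel = table[(table["sensor_a"] == a) & (table["sensor_b"] == b)]
    return sel[["t", "distance_cm"]].rename(columns={"distance_cm": "d"}).reset_index(drop=True)


def clean_dyad(
    table: pd.DataFrame,
    a: str,
    b: str,
    enclosure: EnclosureConfig,
    filters: Optional[FilterConfig] = None,
    feeder_table: Optional[Mapping[str, pd.DataFrame]] = None,
) -> DistanceSeries:
    """Full cleaning chain for one dyad: range → frozen → feeder on each
    directed channel, then replicate averaging."""
    filters = filters or FilterConfig()
    prov = {"raw": 0, "range": 0, "frozen": 0, "feeder": 0}
    cleaned = []
    fa = feeder_table.get(a) if feeder_table else None
    fb = feeder_table.get(b) if feeder_table else None
    for x, y in ((a, b), (b, a)):
        ch = _channel(table, x, y)
        prov["raw"] += len(ch)
        ch, n_range = filter_range(ch, enclosure, min_cm=filters.min_cm)
        ch, n_frozen = filter_frozen(ch, window_s=filters.frozen_s)
        if fa is not None and fb is not None:
            ch, n_feeder = filter_feeder(ch, fa, fb, radius_cm=filters.feeder_cm)
        else:
            n_feeder = 0
        prov["range"] += n_range
        prov["frozen"] += n_frozen
        prov["feeder"] += n_feeder
        cleaned.append(ch)
    averaged = average_replicates(cleaned[0], cleaned[1])
    prov["kept_channel_samples"] = len(cleaned[0]) + len(cleaned[1])
    prov["kept"] = len(averaged)
    return DistanceSeries(dyad=dyad_key(a, b), samples=averaged, provenance=prov)


def clean_all(
    table: pd.DataFrame,
    roster: Iterable[str],
    enclosure: EnclosureConfig,
    filters: Optional[FilterConfig] = None,
) -> tuple[dict, dict]:
    """Clean every dyad in the roster; returns ({dyad: DistanceSeries}, report)."""
    roster = sorted(set(roster))
    feeder_table: Optional[dict[str, pd.DataFrame]] = None
    if (table["sensor_b"] == "feeder").any():
        feeder_table = {
            a: _channel(table, a, "feeder") for a in roster
        }
    series = {}
    for i, a in enumerate(roster):
        for b in roster[i + 1 :]:
            ds = clean_dyad(table, a, b, enclosure, filters=filters, feeder_table=feeder_table)
            if ds.provenance["raw"] > 0:
                series[ds.dyad] = ds
    report = {
        "n_dyads": len(series),
        "per_dyad": {f"{k[0]}-{k[1]}": v.provenance for k, v in series.items()},
    }
    return series, report
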