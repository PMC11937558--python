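"""Absolute and relative interindividual distance statistics.

The relative interindividual distance — median dyadic distance (cm) divided
by the space available per animal (m²) — separates forced from voluntary
proximity: a dyad can be absolutely close but relatively far apart in a
small pen (forced proximity), or absolutely and relatively close in a large
field (voluntary proximity).

Reporting conventions follow the published tables: space per animal is
truncated to 2 decimals, relative distances are rounded half-up to 2
decimals; all internal arithmetic keeps full precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from ._util import round_half_up, truncate
from .cleaning import DistanceSeries
from .config import EnclosureConfig


@dataclass
class DyadSummary:
    dyad: tuple[str, str]
    n_samples: int
    median_cm: float
    ci95_cm: tuple[float, float]
    relative_cm_per_m2: float
    condition: str


def space_per_horse(area_m2: float, n_horses: int) -> float:
    """Enclosure area divided by head count, m² per animal (2 decimals,
    truncated — the convention of the published occupancy table)."""
    if n_horses < 1:
        raise ValueError("n_horses must be >= 1")
    if area_m2 <= 0:
        raise ValueError("area_m2 must be positive")
    return truncate(area_m2 / n_horses, 2)


def median_with_ci(
    d: np.ndarray, n_boot: int = 1000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Sample median with a seeded percentile-bootstrap 95% CI."""
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValueError("empty series")
    med = float(np.median(d))
    if d.size == 1 or np.all(d == d[0]):
        return med, (med, med)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, d.size, size=(n_boot, d.size))
    boots = np.median(d[idx], axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return med, (float(lo), float(hi))


def relative_distance(median_cm: float, space_m2_per_horse: float) -> float:
    """Relative interindividual distance in cm/m² (2 decimals, half-up)."""
    if space_m2_per_horse <= 0:
        raise ValueError("space per horse must be positive")
    return round_half_up(median_cm / space_m2_per_horse, 2)


def summarize_dyads(
    series_by_dyad: Mapping[tuple[str, str], DistanceSeries],
    enclosure: EnclosureConfig,
    condition: str,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-dyad median / CI / relative distance table for one condition."""
    space = space_per_horse(enclosure.area_m2, enclosure.n_horses)
    rows = []
    for k, (dyad, ds) in enumerate(sorted(series_by_dyad.items())):
        if len(ds) == 0:
            continue
        med, (lo, hi) = median_with_ci(ds.d, n_boot=n_boot, seed=seed + k)
        rows.append(
            {
                "animal_a": dyad[0],
                "animal_b": dyad[1],
                "condition": condition,
                "n_samples": len(ds),
                "median_cm": med,
                "ci_lo_cm": lo,
                "ci_hi_cm": hi,
                "relative_cm_per_m2": med / space,
                "space_m2_per_horse": space,
            }
        )
    return pd.DataFrame(rows)


def group_summary(
    dyad_table: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    relative_method: str = "median_of_ratios",
) -> dict:
    """Pooled group statistics over per-dyad medians (equal dyad weighting).

    ``relative_method`` selects how the pooled relative distance is formed:
    ``median_of_ratios`` takes the median of per-dyad relative distances,
    ``ratio_of_medians`` divides the pooled median by the space per animal.
    The choice is reported alongside the values, never silently reconciled.
    """
    if dyad_table.empty:
        raise ValueError("no dyads to summarize")
    if relative_method not in ("median_of_ratios", "ratio_of_medians"):
        raise ValueError(f"unknown relative_method {relative_method!r}")
    medians = dyad_table["median_cm"].to_numpy()
    pooled_med, (lo, hi) = median_with_ci(medians, n_boot=n_boot, seed=seed)
    ratios = dyad_table["relative_cm_per_m2"].to_numpy()
    if relative_method == "median_of_ratios":
        rel, (rlo, rhi) = median_with_ci(ratios, n_boot=n_boot, seed=seed + 1)
    else:
        space = float(dyad_table["space_m2_per_horse"].iloc[0])
        rel = pooled_med / space
        rlo, rhi = lo / space, hi / space
    return {
        "condition": str(dyad_table["condition"].iloc[0]),
        "n_dyads": int(len(dyad_table)),
        "median_cm": pooled_med,
        "ci_lo_cm": lo,
        "ci_hi_cm": hi,
        "relative_cm_per_m2": rel,
        "rel_ci_lo": rlo,
        "rel_ci_hi": rhi,
        "relative_method": relative_method,
    }


def format_summary_row(summary: dict) -> dict:
    """Reporting-layer rounding of a pooled summary (2 decimals, half-up)."""
    out = dict(summary)
    for key in ("median_cm", "ci_lo_cm", "ci_hi_cm", "relative_cm_per_m2", "rel_ci_lo", "rel_ci_hi"):
        out[key] = round_half_up(out[key], 2)
    return out
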