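"""Time-in-proximity bins and closest / least frequent associates.

Fractions are per dyad: the count of retained samples falling in a distance
bin divided by that dyad's total retained samples, so a dyad with patchy
sensor coverage is not penalised. Bins are half-open as conventionally
printed: ≤3 m, (3, 6] m, (6, 9] m, (9, 12] m, with the remainder >12 m.

The closest associate of a focal animal is the partner with the highest
≤3 m fraction (its least frequent associate the lowest); the relation is
deliberately not symmetrised — A's closest associate need not reciprocate.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .cleaning import DistanceSeries

BIN_EDGES_CM = (300.0, 600.0, 900.0, 1200.0)
BIN_LABELS = ("le_3m", "3_6m", "6_9m", "9_12m", "gt_12m")


def time_in_bins(d: np.ndarray) -> dict:
    """Fraction of retained samples per proximity bin (sums to 1 exactly)."""
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValueError("no retained samples for this dyad; fractions undefined")
    # bins are (lo, hi]: a sample at exactly 300 cm belongs to the ≤3 m bin
    counts = np.array(
        [
            int(np.sum(d <= 300.0)),
            int(np.sum((d > 300.0) & (d <= 600.0))),
            int(np.sum((d > 600.0) & (d <= 900.0))),
            int(np.sum((d > 900.0) & (d <= 1200.0))),
            int(np.sum(d > 1200.0)),
        ]
    )
    return dict(zip(BIN_LABELS, counts / d.size))


def association_matrices(
    series_by_dyad: Mapping[tuple[str, str], DistanceSeries],
    animals: list[str],
) -> dict[str, pd.DataFrame]:
    """Symmetric per-bin fraction matrices plus a median-distance matrix.

    Returns {bin label: DataFrame} with an extra key ``"median_cm"``; dyads
    with no retained samples are NaN.
    """
    animals = sorted(animals)
    mats = {lab: pd.DataFrame(np.nan, index=animals, columns=animals) for lab in BIN_LABELS}
    mats["median_cm"] = pd.DataFrame(np.nan, index=animals, columns=animals)
    for (a, b), ds in series_by_dyad.items():
        if len(ds) == 0:
            continue
        fracs = time_in_bins(ds.d)
        for lab in BIN_LABELS:
            mats[lab].loc[a, b] = mats[lab].loc[b, a] = fracs[lab]
        med = float(np.median(ds.d))
        mats["median_cm"].loc[a, b] = mats["median_cm"].loc[b, a] = med
    return mats


def closest_associate(
    animal: str,
    close_fractions: pd.DataFrame,
    median_cm: Optional[pd.DataFrame] = None,
    mode: str = "closest",
) -> str:
    """Partner with the largest (``closest``) or smallest (``least``) ≤3 m
    fraction. Ties break toward the smaller median distance, then the
    lexicographically smaller id."""
    row = close_fractions.loc[animal].drop(labels=[animal]).dropna()
    if row.empty:
        raise ValueError(f"no partner with defined fraction for {animal}")
    best = row.max() if mode == "closest" else row.min()
    cands = sorted(row.index[row == best])
    if len(cands) > 1 and median_cm is not None:
        meds = median_cm.loc[animal, cands]
        cands = sorted(meds.index[meds == meds.min()])
    return cands[0]


def associate_table(
    mats: Mapping[str, pd.DataFrame], animals: list[str], condition: str
) -> pd.DataFrame:
    """Closest and least frequent associate per animal, with their ≤3 m fractions."""
    close = mats["le_3m"]
    med = mats["median_cm"]
    rows = []
    for a in sorted(animals):
        try:
            best = closest_associate(a, close, med, mode="closest")
            worst = closest_associate(a, close, med, mode="least")
        except ValueError:
            continue
        rows.append(
            {
                "animal": a,
                "condition": condition,
                "closest": best,
                "closest_frac_le3m": float(close.loc[a, best]),
                "least_frequent": worst,
                "least_frac_le3m": float(close.loc[a, worst]),
            }
        )
    return pd.DataFrame(rows)


def affiliation_strata(
    mats: Mapping[str, pd.DataFrame],
    associates: pd.DataFrame,
) -> pd.DataFrame:
    """Distributions of median distance and ≤3 m fraction per affiliation
    stratum (closest associates, all dyads, least frequent associates)."""
    close, med = mats["le_3m"], mats["median_cm"]

    def stratum(pairs: set[tuple[str, str]], name: str) -> dict:
        fr = [float(close.loc[a, b]) for a, b in pairs if not np.isnan(close.loc[a, b])]
        md = [float(med.loc[a, b]) for a, b in pairs if not np.isnan(med.loc[a, b])]
        return {
            "stratum": name,
            "n_dyads": len(fr),
            "median_frac_le3m": float(np.median(fr)) if fr else np.nan,
            "median_distance_cm": float(np.median(md)) if md else np.nan,
        }

    closest_pairs = {tuple(sorted((r.animal, r.closest))) for r in associates.itertuples()}
    least_pairs = {tuple(sorted((r.animal, r.least_frequent))) for r in associates.itertuples()}
    animals = list(close.index)
    all_pairs = {
        (a, b) for i, a in enumerate(animals) for b in animals[i + 1 :]
    }
    return pd.DataFrame(
        [
            stratum(closest_pairs, "closest"),
            stratum(all_pairs, "overall"),
            stratum(least_pairs, "least_frequent"),
        ]
    )
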