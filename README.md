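# equiprox

Proximity-sensor analysis of equine social behaviour. `equiprox` turns raw
1 Hz dyadic distance streams from an ultra-wideband (UWB) real-time location
system — the kind of data produced by halter-mounted proximity tags on a
herd of horses — into the quantities behavioural ecologists report:

* **cleaned dyadic distance series** — removal of physically impossible
  readings (above the enclosure diagonal or below 5 cm), stuck-sensor runs
  (no variation for more than 10 s), samples where both animals crowd a hay
  feeder (both within 3 m), then averaging of the two directed technical
  replicates (A→B and B→A);
* **absolute and relative interindividual distance** — per-dyad medians with
  bootstrap 95% CIs, and the relative distance *median (cm) / space per
  horse (m²)*, which separates forced proximity (low absolute, high
  relative) from voluntary proximity (low absolute, low relative);
* **association preferences** — fraction of time per dyad at ≤3 m, 3–6 m,
  6–9 m and 9–12 m, and each animal's closest / least frequent associate
  (the partner with the highest / lowest ≤3 m fraction);
* **median-threshold social networks** — mean dyadic distance matrices
  binarized at the median of the dyad entries (edge iff strictly below),
  with degree, unnormalized betweenness, and reciprocal-farness closeness
  per animal, exported as GraphML and CSV;
* **agonistic event detection** — rule-based approaches (≥100 cm decrease to
  <200 cm within 3 s at ≥85 cm/s mean closing speed, consistent direction,
  two animals only) and linked high-/low-intensity retreats (≥100 cm
  increase within 3 s after an approach, with/without the 85 cm/s speed
  floor), with per-horse-hour rates; speeds above 800 cm/s are discarded as
  measurement errors;
* **nonparametric inference** — a seeded Monte-Carlo Fisher–Pitman
  permutation test for mean differences and Spearman rank correlation.

Because raw tracking data of this kind are rarely shared, the package ships
a first-class **herd simulator**: an attraction–repulsion agent model with
pair-bonded affinity structure, a UWB sensor-noise model (replicate
asymmetry, out-of-range spikes, sub-5 cm artifacts, frozen segments), an
optional feeder, and choreographed agonistic episodes whose exact windows
are recorded as ground truth. Every pipeline stage is validated against
that ground truth.

## Worked example

A single herd of 8 horses, simulated for one hour in a 30 × 15 m paddock
and one hour in a 65 × 40 m field with identical social structure:

```bash
equiprox run-all --config examples/two_enclosures.yaml
```

The run writes per-stage CSVs, GraphML networks and `report.json` into
`runs/two_enclosures/`. With the config's seed (3) the report contains:

| quantity | paddock | field |
|---|---|---|
| pooled median distance (cm) | 887.39 | 2063.28 |
| relative distance (cm/m²) | 15.78 | 6.15 |
| agonistic approaches (per horse-hour) | 2.63 | 0.25 |

and the cross-condition statistics

```
median_distance_permutation: observed_mean_diff_cm = -840.4, p = 0.000999
approaches_vs_distance_spearman = -0.375
```

Read: the herd stands absolutely closer in the paddock (887 vs 2063 cm,
permutation p ≈ 0.001) but *relatively* farther apart for the space
available (15.8 vs 6.2 cm/m²) — forced, not voluntary, proximity — and
crowding raises the agonistic approach rate roughly tenfold, with event
counts correlating negatively with dyadic distance.

Each stage is also exposed as a subcommand (`simulate`, `clean`, `metrics`,
`associations`, `network`, `events`, `report`) over the same config, and as
plain library functions (`equiprox.clean_all`, `equiprox.detect_events`,
`equiprox.build_network`, ...) for use on real CSV exports
(`timestamp,sensor_a,sensor_b,distance_cm`).

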