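# Methods

This note records the models, conventions and numerical choices behind
`equiprox`, in the order the pipeline applies them.

## Sensor data model

The unit of observation is the *dyad* — an unordered pair of animals. A UWB
real-time location system reports the distance between every ordered pair
of tags once per second (two directed "technical replicate" channels per
dyad), in centimetres. The package's canonical containers are a long-format
table (`t`, `sensor_a`, `sensor_b`, `distance_cm`) for raw channels and a
per-dyad `DistanceSeries` (strictly increasing epoch seconds, distances in
cm, provenance counts) after cleaning. Gaps are left as gaps; nothing is
interpolated.

## Cleaning

Four rules, applied per directed channel in this order, then replicate
averaging:

1. **Range** — drop readings above the enclosure diagonal
   (100·√(length² + width²) cm, the largest distance two animals inside the
   fence can have) or below 5 cm (impossible given tag placement).
2. **Frozen runs** — drop, in full, every maximal run of bit-identical
   consecutive values lasting *more than* 10 s. Identity is exact
   (tolerance 0): genuine UWB readings are inherently variable, so exact
   constancy marks a stuck channel. A run of exactly 10 identical 1 Hz
   samples survives; 11 or more are removed.
3. **Feeder** — when a feeder channel exists, drop samples where *both*
   animals are concurrently within 300 cm of the feeder (forced proximity);
   one animal near the feeder is fine. Concurrency is the nearest feeder
   sample within ±1 s. Without a feeder channel this is a warned no-op.
4. **Replicate averaging** — per timestamp, the mean of the available
   directed channels; a timestamp present in only one channel keeps that
   value.

Frozen-run detection runs on raw channels *before* averaging because a
freeze is a failure of one sensor pairing; averaging first would dilute it.
Duplicate timestamps within a channel are collapsed by their mean at load
time. Provenance counts satisfy raw = kept + Σ removed-per-filter and all
filters are idempotent.

## Distance metrics

Per dyad: sample median with a seeded percentile-bootstrap 95% CI (1000
resamples by default; the CI method is a package choice — the width agrees
with the exact binomial order-statistic interval in tests). The *relative
interindividual distance* is median (cm) divided by space per animal
(enclosure area / head count, m²).

Pooled group statistics are computed over per-dyad medians (one value per
dyad), not over pooled raw samples, so dyads with more retained samples do
not dominate. Two pathways exist for the pooled relative distance — the
median of per-dyad ratios (default) and the pooled median divided by the
space per animal — and the output labels which was used (`relative_method`);
published tables are ambiguous between the two, so neither is silently
preferred.

Reporting conventions: space per animal is *truncated* to 2 decimals (the
convention that reproduces the published occupancy table, e.g. 480 m² / 11
animals → 43.63), relative distances and rates are rounded half-up to 2
decimals. Internal arithmetic keeps full precision.

## Associations

Per-dyad time fractions in the bins ≤3 m, (3, 6] m, (6, 9] m, (9, 12] m and
>12 m, with the dyad's own retained-sample count as denominator, so the
five fractions sum to exactly 1. The 300 cm boundary belongs to the close
bin. The closest (least frequent) associate of an animal is the partner
with the highest (lowest) ≤3 m fraction; ties break toward the smaller
median distance, then the lexicographically smaller id. The relation is
deliberately not symmetrised, and associates are identified per condition.

## Networks

Mean dyadic distance over the whole observation period → threshold at the
median of the upper-triangle entries → edge iff *strictly below* the
threshold (ties at the median yield no edge; an all-equal matrix yields an
empty graph, with a warning). Centrality conventions, chosen for internal
consistency with published per-animal values (a degree-5 hub in a six-node
component scoring closeness 0.2; isolated animals scoring 0 everywhere):

* degree — raw count of direct ties;
* betweenness — unnormalized shortest-path betweenness on the unweighted
  graph, each unordered pair counted once, fractional credit split equally
  among equally short paths (networkx `normalized=False`);
* closeness — 1 / (sum of shortest-path lengths to reachable nodes),
  unnormalized, 0 for isolated nodes.

Betweenness and closeness are verified against a brute-force all-paths
enumeration on every graph with ≤5 nodes and sampled 6-node graphs.
GraphML export carries centralities as node attributes and the mean dyadic
distance as the edge attribute (the natural candidate for the otherwise
unspecified edge weight).

## Agonistic events

Instantaneous speed is the signed per-step distance change over the actual
sampling interval; magnitudes above 800 cm/s are physically impossible for
the animals and flag the later sample as a measurement error, excluding it
from event logic.

An **approach** is a window of consecutive 1 Hz samples (unit steps only,
so no event spans a cleaning gap), at most 3 s long, with: total decrease
≥100 cm, final distance <200 cm, window-mean closing speed ≥85 cm/s, and
per-step monotone decrease within a 1 cm jitter tolerance ("consistent
direction" — only scalar distances exist, no headings). The speed floor is
applied to the window mean by default (`speed_floor_mode="window"`): at
1 Hz, jitter makes per-step floors brittle, and the mean is the speed the
displacement criteria already determine; a per-step mode is available.
Overlapping qualifying windows of a dyad merge into one event (earliest
start, latest end). Two candidate events that share an animal and overlap
in time void each other — a conservative reading of "only two animals per
event". Threshold comparisons carry a 10⁻⁶ cm tolerance so a drop of
exactly 100 cm qualifies regardless of float representation.

A **retreat** is a ≥100 cm rise within ≤3 s starting within 3 s after an
approach ends (the lag is configurable; "following an approach" needs a
bound), direction-consistent, linked to that approach (at most one retreat
per approach, the earliest qualifying cluster). It is **high-intensity** if
its *earliest qualifying window* has mean speed ≥85 cm/s, else
**low-intensity**; classifying by the earliest window keeps ordinary herd
motion that merges onto the tail of the flight from re-grading the event in
either direction. A fast retreat is never double-counted as low-intensity.

Rates: events / (animals × tracking hours); with animals = 1 this is the
pooled per-group-hour rate. cm/s → km/h is ×0.036.

## Herd simulator

The simulator is a validation harness with ground truth, not a claim about
equine locomotion (no published movement model exists for these data).

**Social forces** (overdamped, 1 s Euler steps, speeds in m/s): hard-core
repulsion below 1 m; linear repulsion up to the per-dyad equilibrium
distance `eq = equilibrium_dist_m · (2 − affinity)` (default 3 m at
affinity 1); attraction `0.15 · affinity² · (d − eq − 50·(1 − affinity)²)`
beyond an affinity-dependent dead zone, capped at 0.3 m/s. The dead zone
makes cohesion scale with bond strength: pair-bonded animals (affinity
~0.9) hold station at 3–4 m while weakly bonded dyads drift apart for tens
of metres before group cohesion pulls back — so the same herd packs a pen
at wall-limited spacing but spreads across a field, reproducing the
absolute-up / relative-down pattern between enclosures. Each agent also
carries an Ornstein–Uhlenbeck wander velocity (sd 0.15 m/s, a calm grazing
pace) and free agents give ongoing confrontations a wide berth (≤0.4 m/s
push within 3.5 m of a busy animal). Boundaries reflect; non-event speed is
capped at 3 m/s. The default affinity structure pairs consecutive animals
as strong associates (0.85–0.95) over a loose background (0.1–0.4).

**Choreographed episodes** (scripted or spontaneous) override the forces
for their dyad in three legs: a *setup* leg walks the pair (at 0.8 m/s,
below the 85 cm/s approach floor, so setup can never register as an event
on any dyad) to a 3.2 m standoff with ≥4 m wall clearance and clear
approach and escape corridors; an *approach* leg closes in a straight line
at the configured speed (default 100 cm/s) until the dyad is below 1.5 m;
a *flight* leg recedes for 3 s at 1.3 m/s (high-intensity) or 0.6 m/s
(low-intensity) along the clearest lane within ±45° of straight-away. Hard
positional floors — 2.2 m from every uninvolved animal (enforced against
their end-of-tick positions, by exclusion-circle projection and sliding
along exact-distance rings) and the 3.2 m setup standoff — guarantee that
no choreography leg can end a qualifying window below the 200 cm approach
end-distance against any third party. A setup that cannot find clear
corridors within 40 s aborts and retries shortly (scripted episodes) or
lapses (spontaneous ones). The flight speeds sit deliberately on either
side of the 85 cm/s classifier: the low flight's fastest possible window is
60 cm/s, the high flight's slowest first window ≈ 1.3·cos 45° ≈ 92 cm/s,
so each completed episode satisfies all four approach criteria and exactly
one retreat definition by construction. Ground truth records the approach
and flight windows of every completed episode.

**Spontaneous aggression** models conflict as personal-space violation: a
free dyad closer than 0.85× its own equilibrium distance (but ≥3 m, which
excludes bonded pairs whose tolerance is higher than that floor) initiates
an episode with hazard 0.02 per pair-second, scaled by how many other
animals crowd the pair within 8 m. Under identical social structure this
makes the agonistic event rate an emergent function of enclosure size.

**Sensor model**: per dyad, common-mode jitter (default sd 2 cm) shared by
both directed channels plus independent per-channel replicate noise
(default sd 3 cm, so the channel-difference sd is √2·3 cm); out-of-range
spikes (probability 10⁻³ per channel-sample, values above the enclosure
diagonal), sub-5 cm artifacts (5·10⁻⁴), and configurable frozen segments.
Every injected artifact sample is logged in the ground truth. An optional
feeder at the enclosure centre draws agents into dwell bouts (~120 s,
started at hazard 1/900 per free agent-second), producing the forced
co-proximity the feeder filter removes.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: biomechanical gait and heading, terrain and
shelter use, clock drift between tags, distance-dependent or multipath-
structured (non-Gaussian) sensor error, and social dynamics beyond a static
affinity matrix with dyadic episodes (no coalitions, no dominance
hierarchy). Validation results on simulated herds bound the pipeline's
correctness, not the biology.

## Statistics

The Fisher–Pitman permutation test permutes pooled group labels with a
seeded generator (default 1000 iterations) and reports the two-sided
Monte-Carlo p for the absolute difference of means with the add-one
correction p = (1 + #{|permuted| ≥ |observed|}) / (1 + iterations), so p is
never 0 and the test is slightly conservative; type-I error at α = 0.05 is
calibrated to 5% ± 1% in the acceptance suite. Degenerate input (all values
identical) returns p = 1. Spearman correlation is the Pearson correlation
of mid-ranks (scipy); constant input warns and returns NaN.

## Problem sizes

Validation runs use sizes chosen to exercise each property well: event
recovery uses 200 choreographed episodes among 8 agents in a 30 × 15 m pen
(~3.4 h of 1 Hz data; episodes spaced 60 s), with and without sensor noise;
artifact filtering uses ~650 injected artifact samples among ~100k clean
ones; the centrality oracle covers all 1 096 graphs on ≤5 nodes plus 300
sampled 6-node graphs; permutation calibration uses 2000 null replicates of
15 + 15 normal samples; the two-enclosure comparison simulates 4 h per
condition with the default spontaneous-aggression scenario.

## Known limitations

* The four cleaning rules are applied in a fixed order (range → frozen →
  feeder → averaging); published descriptions do not state an order, and a
  different one would change provenance counts at the margins.
* The merged-event convention means a long monotone closing produces one
  approach whose window may exceed 3 s; the 3 s bound applies to the
  qualifying windows, not the merged report.
* Exact reproduction of published per-animal centralities, distance medians
  and model fits requires the original tracking data, which are not
  deposited; oracle equivalence and simulator ground truth stand in for
  them.
* Linear mixed-effects models and stepwise regression on the derived
  summaries are out of scope; the exported CSVs are shaped for use with
  standard statistics packages.
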