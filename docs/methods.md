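# Methods

## Data model

Four record streams per participant, all timestamped in the participant's
local clock (naive ISO-8601; the analysis reasons about daily routines, for
which civil local time is the natural frame):

| stream    | record                              | cadence                         |
|-----------|-------------------------------------|---------------------------------|
| gps       | (timestamp, lat, lon)               | event-driven (phone activity)   |
| proximity | (timestamp, beacon_id, detected, rssi) | one completed scan / 15 min  |
| activity  | (timestamp, label)                  | one reading / 15 min            |
| audio     | (clip_start, duration, [(class, score)…]) | one 30 s clip / 15 min in a capture window |

Files follow the collector convention `<ID>-<TYPE>_<YYYYMMDD>.<ext>` (weekly
audio table `<ID>-AUDIO.csv`, raw clips `<ID>-EAR_<YYYYMMDDHHMMSS>.m4a`).
The collector app never published its CSV columns, so the schemas above are
canonical for this package, chosen as the minimal columns that support every
downstream operation. Both `.txt` and `.csv` extensions are accepted. Raw
`.m4a` clips are registered in provenance but never decoded — clip-level
audio classification is upstream of this package; we consume its prediction
table.

Ingest dedupes on (datatype, full record), because weekly re-uploads
overlap; a rescan of the same folder is a no-op. Rows failing the schema are
skipped and counted; a file with > 50 % bad rows is rejected as corrupt.

## Rhythm coding

A day is 96 half-open 15-minute bins from local midnight; an hour is 4
consecutive bins. Bins with no record are explicitly missing, never
imputed. Hour codes are presence rules (see README). Two genuinely open
choices and how we resolved them:

- **`apart` vs `no_data`.** A third state distinct from "no data" requires
  scan events that completed without a detection. Our proximity schema
  records those explicitly; a store containing only detection events
  degrades gracefully to {together, no_data}.
- **`unknown` activity labels** carry no evidence: an hour of only `unknown`
  is `no_data`, not `inactive`. Stillness must be observed to be coded.
- **Speech qualification** is a label in a configurable speech-class set
  (default `{"Speech"}`) with score ≥ 0.5. The upstream classifier's
  vocabulary and operating threshold are deployment-specific, so both are
  parameters.

The day-level speech percentage is over clips, not hours: 100 × qualifying
clips / captured clips, missing when no clips were captured.

## Mobility

Distances are haversine great-circle distances with Earth radius
6,371,000 m (so 1° of arc = 111,194.93 m). Radius of movement is the radius
of gyration about the spherical centroid (unit-vector mean). "Farthest
distance traveled" is operationalized as farthest *from home*, not
cumulative path length: GPS fixes are event-driven and irregular, so path
length would measure phone usage more than movement.

Home is the centroid of the modal night-window (00:00–06:00) heat-map cell,
falling back to the modal all-day cell when the phone records no night
fixes; ties break deterministically toward the larger, then
lexicographically smaller cell. Defaults: home radius 100 m, heat-map cell
0.0005° (~55 m), standard values at village scale in the digital-phenotyping
literature. Time outside home is the share of *observed* 15-minute bins
whose last fix lies beyond the home radius — unobserved bins are excluded
from the denominator rather than assumed to be at home.

Heat maps are plain fix-count grids over the fixes' bounding box (the
upstream product rendered them on map tiles; only the count-grid semantics
are reproducible, and rendering is an optional matplotlib export).

## Awards and goals

Rules are declarative: (channel, statistic, state, comparator, threshold,
window). Day-window rules grant one award per qualifying day; week-window
rules grant once per week when at least `min_days` days individually
qualify (`min_days` is our extension so that "have at least one speech day
this week" is expressible with the same statistic vocabulary). Award
identity is (participant, rule, period), so re-evaluation can never
duplicate, and ≥-rules are monotone: more qualifying hours never revoke an
award. The default thresholds (active ≥ 4 h/day, together ≥ 8 h/day, any
observed time outside home) are placeholders for counselor-configured
goals — the pilot never formalized its milestone thresholds — and the
message catalog is likewise placeholder text, not the study's cards.

## Synthetic schedule simulator

The generator emulates the pilot's sampling regime: proximity scans and
activity readings every 15 minutes around the clock; one 30-second clip
every 15 minutes inside a daytime audio capture window; GPS fixes as a
Poisson process (default mean 4/hour) during waking hours (06:00–22:00),
standing in for fixes taken at phone-use events. The deployment's reported
volumes — seven day-files per sensor and 280 clips (~40/day) per week —
pin the audio window at 10 hours (default 08:00–18:00): a full 24-hour
window at 15-minute cadence would give 96 clips/day, which contradicts the
reported 40/day, so the window resolves that tension explicitly and
configurably.

The latent routine is a list of within-day episodes: trips (destination at
a configurable offset due north of home), mother–infant separations
(scans report no detection), speech episodes (clips draw a Speech label
with the episode's probability), and activity bouts. Ground truth per day —
24×3 true hour labels, true home, true outside fraction (trip-covered
waking bins / waking bins) — is derived from the schedule and the realized
speech draws *before* dropout, so it describes the routine rather than the
surviving records.

Default episode boundaries are aligned to hour/15-minute edges and default
speech-episode probability is 1.0. This makes every hour
evidence-homogeneous, which is what gives the simulator its clean
degradation guarantee: under independent per-record dropout a coded hour
can fall to `no_data` but can never flip to a wrong observed state. With
episodes cutting through an hour that guarantee is provably unattainable
(dropout can erase the minority evidence), so the recovery suites use
aligned routines; the oracle-equivalence suite (grid coding vs direct raw
scanning) deliberately uses unaligned episodes, mixed cadences of 5–30
minutes, and dropout up to 0.5, where no such structure is assumed.

Determinism: each (seed, date) pair seeds an independent PCG64 stream, so a
week is reproducible file-for-file byte-identically, and simulating day 3
does not depend on whether days 1–2 were generated.

What the simulator does **not** emulate — and hence what passing tests do
not show about field data: GPS noise and urban canyon effects, beacon RSSI
attenuation and intermittent detections at range, classifier errors in the
audio predictions (labels are drawn from the latent schedule, not from
audio), multi-destination trips, and infant-side sensors. Recovery results
on synthetic weeks validate the pipeline's bookkeeping, not the sensors.

## Problem sizes and numerical choices

The test and acceptance workloads use one participant-week of defaults
(~2,100 records) plus batches of 50–200 randomized single days, which keep
the full suite in seconds while exercising every code path; all randomized
tests are seeded. Floats are written with `repr` round-tripping, so
write→read is exact equality, and JSON/CSV exports are byte-stable across
reruns. Degenerate inputs follow one rule: absence of evidence is `missing`
(`None`), never zero — empty days code to `no_data`, zero fixes yield
missing mobility features, zero clips a missing speech percentage.

## Known limitations

- A single home per participant; no relocation mid-study.
- `fraction_time_outside_home` conditions on observed bins; when phone use
  correlates with being away from home the estimate is biased upward.
- Hour coding is presence-based by design: a single spurious detection
  flips an hour to `together`/`active`/`speech`. That matches the upstream
  operationalization but makes the codes sensitive to false positives.
- The proximity chart's three states require explicit failed-scan rows;
  collectors that log only detections lose the `apart` state.
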