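# dyadsense

A passive-sensing pipeline for mother–infant digital phenotyping in
low-resource psychosocial counseling programs.

A depressed mother's low-cost Android phone can passively capture four
streams of behavioral evidence: the auditory environment (speech around her,
a proxy for social interaction), physical activity versus sedentary behavior,
GPS movement through her community, and mother–infant closeness via a
Bluetooth beacon on the infant's clothing. `dyadsense` turns the weekly
upload of those raw sensor logs into the material a lay counselor can use in
a behavioral-activation session: hourly together/apart, active/inactive and
speech/no-speech codings, GPS mobility summaries, motivational award cards,
and an offline weekly report — plus a synthetic daily-schedule simulator so
the whole pipeline is testable without devices or field data.

## What it computes

Sensor records are quantized onto a 96-bin **15-minute day grid** per
channel, with missing bins preserved, and coded hour by hour with presence
rules:

- **proximity** — hour *h* is `together` if any Bluetooth scan in *h*
  detected the infant's beacon, `apart` if scans completed without a
  detection, `no_data` if no scan ran;
- **activity** — `active` if any reading in *h* is a non-still label
  (walking, running, in_vehicle, cycling), `inactive` if only stillness was
  observed;
- **speech** — `speech` if any 30-second audio clip in *h* carries a
  speech-class label with score ≥ 0.5;
- **speech count percentage** — 100 × (speech clips) / (all clips) per day.

From event-driven GPS fixes it derives, per day:

- **radius of movement** (radius of gyration)
  `r_g = sqrt( (1/n) Σᵢ d(xᵢ, x̄)² )`, the RMS haversine distance of the
  day's fixes from their spherical centroid;
- **farthest distance from home**, `max_i d(xᵢ, home)`, with home estimated
  as the modal night-time (00:00–06:00) heat-map cell;
- **fraction of observed 15-minute bins spent outside home** (> 100 m);
- **heat-map grids** of fix counts on a ~55 m lat/lon grid.

Declarative award rules over the coded days (speech-present day, active
hours ≥ k, together hours ≥ k, left-home day) trigger motivational messages,
and weekly goals linked to rules are resolved met/unmet.

## Worked example

Simulate a week of sensor files (the default schedule: a 10-hour audio
window giving 40 clips/day, a daily two-hour market trip 1.5 km from home, a
two-hour afternoon separation, morning and evening speech episodes, two
walking bouts), then build the counselor's weekly report:

```
$ dyadsense simulate inbound --seed 11
wrote 22 files (280 audio clips) to inbound

$ dyadsense report inbound SS0001 2019-06-05 --out week1
wrote 4 files to week1
completeness (% observed hours): activity=100.0, gps=66.7, proximity=100.0, speech=41.7

$ dyadsense mobility inbound SS0001 | head -3
home estimate: (27.700000, 85.333000), support=397
2019-06-05: n_fixes=62 radius=474.7m farthest=1500.0m outside=0.136
2019-06-06: n_fixes=67 radius=458.8m farthest=1500.0m outside=0.114
```

The 22 files are 7 GPS + 7 proximity + 7 activity day-files plus one weekly
audio-prediction table — the file accounting of a one-week device
retrieval. Proximity and activity are sampled every 15 minutes around the
clock, so their completeness is 100%; audio is only captured during the
10-hour daytime window (10/24 ≈ 41.7%); GPS fixes are event-driven and reach
two thirds of the hours. The home estimate recovers the configured home
coordinates, `farthest=1500.0m` is the configured trip offset, and
`outside≈0.125` matches the two-hour trip in a 16-hour waking day
(8/64 bins). `week1/` holds `report.json` with chart-ready data blocks, the
tidy `codes.csv` and `mobility.csv` tables, and `awards.csv` with the
granted award cards (speech day, together day, left-home day).

The same workflow is available as library calls
(`dyadsense.simulate_week`, `dyadsense.run_week`, `dyadsense.export_report`).

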