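"""Synthetic daily-schedule simulator with ground truth.

Generates collector-convention sensor files from a latent daily routine —
home location, trips away from home, mother–infant separation episodes,
speech episodes, activity bouts — so that every pipeline stage can be tested
end-to-end without devices or field data collection.

The default configuration reproduces the sampling regime of a one-week
deployment: proximity scans and activity readings every 15 minutes around
the clock, one 30-second audio clip every 15 minutes during a 10-hour
daytime capture window (40 clips/day, 280 per week), and event-driven GPS
fixes drawn from a Poisson process (mean 4/hour) during waking hours —
emulating fixes taken whenever the phone is in use.  Episode boundaries in
the default schedule are aligned to 15-minute bins, which keeps each hour's
evidence homogeneous: under record dropout a coded hour can degrade to
``no_data`` but never flip to a wrong observed state.

Every simulated day also yields a :class:`ScheduleGroundTruth` holding the
true per-hour proximity/activity/speech labels, the true home, and the true
fraction of waking time spent outside the home — the oracle for the
pipeline's recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .ebm_io import (
    ActivityReading,
    AudioClipPrediction,
    FileMeta,
    GpsFix,
    ProximityReading,
    write_sensor_file,
)
from .rhythm import NOT_STILL

__all__ = [
    "Episode",
    "SpeechEpisode",
    "ActivityBout",
    "Trip",
    "ScheduleConfig",
    "GroundTruthDay",
    "ScheduleGroundTruth",
    "DaySim",
    "SimulationResult",
    "simulate_day",
    "simulate_week",
    "load_config",
    "METERS_PER_DEG_LAT",
]

METERS_PER_DEG_LAT = 6_371_000.0 * np.pi / 180.0  # ≈ 111,195 m

_NON_SPEECH_CLASSES = ("Music", "Vehicle", "Insect")


def _minutes(t: time) -> int:
    return t.hour * 60 + t.minute


@dataclass(frozen=True)
class Episode:
    """A half-open [start, end) within-day interval."""

    start: time
    end: time

    def __post_init__(self) -> None:
        if _minutes(self.start) >= _minutes(self.end):
            raise ValueError(f"episode start {self.start} must precede end {self.end}")

    def covers(self, minute: int) -> bool:
        return _minutes(self.start) <= minute < _minutes(self.end)


@dataclass(frozen=True)
class SpeechEpisode(Episode):
    probability: float = 1.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("speech probability must be in [0,1]")


@dataclass(frozen=True)
class ActivityBout(Episode):
    label: str = "walking"


@dataclass(frozen=True)
class Trip(Episode):
    """Time away from home at a destination offset (meters, due north)."""

    offset_m: float = 1000.0


def _default_trips() -> list[Trip]:
    return [Trip(time(10, 0), time(12, 0), 1500.0)]


def _default_separations() -> list[Episode]:
    return [Episode(time(13, 0), time(15, 0))]


def _default_speech() -> list[SpeechEpisode]:
    return [
        SpeechEpisode(time(8, 0), time(10, 0), 1.0),
        SpeechEpisode(time(17, 0), time(18, 0), 1.0),
    ]


def _default_bouts() -> list[ActivityBout]:
    return [
        ActivityBout(time(8, 0), time(9, 0), "walking"),
        ActivityBout(time(16, 0), time(17, 0), "walking"),
    ]


@dataclass
class ScheduleConfig:
    """Latent daily routine and sampling regime for the simulator."""

    participant_id: str = "SS0001"
    seed: int = 0
    start_date: date = date(2019, 6, 5)
    n_days: int = 7
    sampling_interval_min: int = 15
    audio_window: tuple[time, time] = (time(8, 0), time(18, 0))
    clip_duration_s: float = 30.0
    home_lat: float = 27.700
    home_lon: float = 85.333
    trips: list[Trip] = field(default_factory=_default_trips)
    separations: list[Episode] = field(default_factory=_default_separations)
    speech_episodes: list[SpeechEpisode] = field(default_factory=_default_speech)
    activity_bouts: list[ActivityBout] = field(default_factory=_default_bouts)
    dropout: float = 0.0
    gps_rate_per_hour: float = 4.0
    awake_window: tuple[time, time] = (time(6, 0), time(22, 0))
    beacon_id: str = "BEACON01"

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.sampling_interval_min <= 0 or self.sampling_interval_min > 1440:
            raise ValueError("sampling interval must be within one day")
        for win in (self.audio_window, self.awake_window):
            if _minutes(win[0]) >= _minutes(win[1]):
                raise ValueError("window start must precede end")


@dataclass
class GroundTruthDay:
    """True hour labels and mobility facts for one simulated day."""

    date: date
    proximity: list[str]  # 24 × {together, apart, no_data}
    activity: list[str]  # 24 × {active, inactive, no_data}
    speech: list[str]  # 24 × {speech, no_speech, no_data}
    outside_fraction: float
    n_clips: int
    n_speech_clips: int


@dataclass
class ScheduleGroundTruth:
    home_lat: float
    home_lon: float
    days: dict[date, GroundTruthDay] = field(default_factory=dict)


@dataclass
class DaySim:
    """One simulated day: per-sensor records plus its ground truth."""

    date: date
    gps: list[GpsFix]
    proximity: list[ProximityReading]
    activity: list[ActivityReading]
    audio: list[AudioClipPrediction]
    truth: GroundTruthDay


@dataclass
class SimulationResult:
    config: ScheduleConfig
    days: list[DaySim]
    truth: ScheduleGroundTruth
    files: list[FileMeta] = field(default_factory=list)


def _day_rng(config: ScheduleConfig, day: date) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, day.toordinal()]))


def _covered(episodes: Sequence[Episode], minute: int) -> Episode | None:
    for ep in episodes:
        if ep.covers(minute):
            return ep
    return None


def _drop(records: list, rng: np.random.Generator, rate: float) -> list:
    if rate <= 0.0 or not records:
        return records
    keep = rng.random(len(records)) >= rate
    return [r for r, k in zip(records, keep) if k]


def simulate_day(config: ScheduleConfig, day: date) -> DaySim:
    """Simulate one day of sensor records from the configured routine.

    Deterministic: the same (config.seed, day) always yields identical
    records.  Ground-truth hour labels are derived from the schedule (and,
    for speech, from the realized per-clip draws) before dropout is applied,
    so they describe the latent routine, not the surviving records.
    """
    rng = _day_rng(config, day)
    pid = config.participant_id
    interval = config.sampling_interval_min
    midnight = datetime.combine(day, time(0, 0))
    cadence = list(range(0, 1440, interval))

    # --- proximity: one completed beacon scan per cadence tick, all day
    proximity: list[ProximityReading] = []
    for m in cadence:
        detected = _covered(config.separations, m) is None
        rssi = round(float(rng.normal(-65.0, 5.0)), 1) if detected else None
        proximity.append(
            ProximityReading(
                pid, midnight + timedelta(minutes=m), config.beacon_id, detected, rssi
            )
        )

    # --- activity: bout label at covered ticks, still otherwise
    activity: list[ActivityReading] = []
    for m in cadence:
        bout = _covered(config.activity_bouts, m)
        label = bout.label if bout is not None else "still"
        activity.append(ActivityReading(pid, midnight + timedelta(minutes=m), label))

    # --- audio: one clip per cadence tick inside the capture window
    audio: list[AudioClipPrediction] = []
    speech_flags: dict[int, bool] = {}  # cadence minute -> drew speech
    a_start, a_end = (_minutes(t) for t in config.audio_window)
    for m in cadence:
        if not a_start <= m < a_end:
            continue
        ep = _covered(config.speech_episodes, m)
        p = ep.probability if ep is not None else 0.0
        is_speech = bool(rng.random() < p)
        speech_flags[m] = is_speech
        if is_speech:
            labels = (("Speech", round(0.6 + 0.39 * float(rng.random()), 3)),)
        else:
            cls = str(rng.choice(_NON_SPEECH_CLASSES))
            labels = ((cls, round(0.5 + 0.45 * float(rng.random()), 3)),)
        audio.append(
            AudioClipPrediction(
                pid, midnight + timedelta(minutes=m), config.clip_duration_s, labels
            )
        )

    # --- GPS: Poisson fix events during waking hours; home unless on a trip
    gps: list[GpsFix] = []
    w_start, w_end = (_minutes(t) for t in config.awake_window)
    for hour_start in range(w_start, w_end, 60):
        n = int(rng.poisson(config.gps_rate_per_hour))
        offsets = np.sort(rng.uniform(0.0, 60.0, size=n))
        for off in offsets:
            m = hour_start + float(off)
            trip = _covered(config.trips, int(m))
            lat = config.home_lat + (trip.offset_m / METERS_PER_DEG_LAT if trip else 0.0)
            gps.append(GpsFix(pid, midnight + timedelta(minutes=m), lat, config.home_lon))
    gps = [replace(f, timestamp=f.timestamp.replace(microsecond=0)) for f in gps]

    truth = _ground_truth_day(config, day, cadence, speech_flags)

    # --- dropout, applied independently per record
    rate = config.dropout
    proximity = _drop(proximity, rng, rate)
    activity = _drop(activity, rng, rate)
    audio = _drop(audio, rng, rate)
    gps = _drop(gps, rng, rate)
    return DaySim(day, gps, proximity, activity, audio, truth)


def _ground_truth_day(
    config: ScheduleConfig,
    day: date,
    cadence: Sequence[int],
    speech_flags: dict[int, bool],
) -> GroundTruthDay:
    prox, act, speech = [], [], []
    for h in range(24):
        ticks = [m for m in cadence if h * 60 <= m < (h + 1) * 60]
        if not ticks:
            prox.append("no_data")
            act.append("no_data")
        else:
            apart = all(_covered(config.separations, m) is not None for m in ticks)
            prox.append("apart" if apart else "together")
            bouts = [_covered(config.activity_bouts, m) for m in ticks]
            active = any(b is not None and b.label in NOT_STILL for b in bouts)
            act.append("active" if active else "inactive")
        clip_ticks = [m for m in ticks if m in speech_flags]
        if not clip_ticks:
            speech.append("no_data")
        else:
            speech.append("speech" if any(speech_flags[m] for m in clip_ticks) else "no_speech")

    w_start, w_end = (_minutes(t) for t in config.awake_window)
    awake_bins = [k for k in range(96) if w_start <= k * 15 + 7.5 < w_end]
    outside = sum(1 for k in awake_bins if _covered(config.trips, int(k * 15 + 7)) is not None)
    frac = outside / len(awake_bins) if awake_bins else 0.0
    return GroundTruthDay(
        date=day,
        proximity=prox,
        activity=act,
        speech=speech,
        outside_fraction=frac,
        n_clips=len(speech_flags),
        n_speech_clips=sum(speech_flags.values()),
    )


def simulate_week(
    config: ScheduleConfig, out_folder: str | Path | None = None
) -> SimulationResult:
    """Simulate ``config.n_days`` consecutive days; optionally write files.

    When ``out_folder`` is given, one GPS, one PROXIMITY and one ACTIVITY
    day-file is written per day, plus a single dateless weekly AUDIO table —
    the exact inbound layout of a one-week device retrieval.
    """
    days = [config.start_date + timedelta(days=i) for i in range(config.n_days)]
    sims = [simulate_day(config, d) for d in days]
    truth = ScheduleGroundTruth(config.home_lat, config.home_lon)
    for sim in sims:
        truth.days[sim.date] = sim.truth
    result = SimulationResult(config, sims, truth)

    if out_folder is not None:
        out_folder = Path(out_folder)
        out_folder.mkdir(parents=True, exist_ok=True)
        pid = config.participant_id
        for sim in sims:
            for records, dtype in (
                (sim.gps, "GPS"),
                (sim.proximity, "PROXIMITY"),
                (sim.activity, "ACTIVITY"),
            ):
                meta = write_sensor_file(
                    records,
                    out_folder,
                    datatype=dtype,
                    participant_id=pid,
                    file_date=sim.date,
                )
                result.files.append(meta)
        all_clips = [clip for sim in sims for clip in sim.audio]
        meta = write_sensor_file(
            all_clips, out_folder, datatype="AUDIO", participant_id=pid
        )
        result.files.append(meta)
    return result


# ---------------------------------------------------------------------------
# Scenario files
# ---------------------------------------------------------------------------


def _parse_time(text: str) -> time:
    h, m = text.split(":")
    return time(int(h), int(m))


def load_config(path: str | Path) -> ScheduleConfig:
    """Load a YAML scenario file into a :class:`ScheduleConfig`.

    Times are ``"HH:MM"`` strings; episode lists are mappings with
    ``start``/``end`` plus episode-specific fields (``offset_m``,
    ``probability``, ``label``).
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    simple = (
        "participant_id",
        "seed",
        "n_days",
        "sampling_interval_min",
        "clip_duration_s",
        "home_lat",
        "home_lon",
        "dropout",
        "gps_rate_per_hour",
        "beacon_id",
    )
    for key in simple:
        if key in raw:
            kwargs[key] = raw[key]
    if "start_date" in raw:
        kwargs["start_date"] = date.fromisoformat(str(raw["start_date"]))
    for key in ("audio_window", "awake_window"):
        if key in raw:
            kwargs[key] = (_parse_time(raw[key][0]), _parse_time(raw[key][1]))
    if "trips" in raw:
        kwargs["trips"] = [
            Trip(_parse_time(e["start"]), _parse_time(e["end"]), float(e.get("offset_m", 1000.0)))
            for e in raw["trips"]
        ]
    if "separations" in raw:
        kwargs["separations"] = [
            Episode(_parse_time(e["start"]), _parse_time(e["end"])) for e in raw["separations"]
        ]
    if "speech_episodes" in raw:
        kwargs["speech_episodes"] = [
            SpeechEpisode(
                _parse_time(e["start"]), _parse_time(e["end"]), float(e.get("probability", 1.0))
            )
            for e in raw["speech_episodes"]
        ]
    if "activity_bouts" in raw:
        kwargs["activity_bouts"] = [
            ActivityBout(_parse_time(e["start"]), _parse_time(e["end"]), e.get("label", "walking"))
            for e in raw["activity_bouts"]
        ]
    return ScheduleConfig(**kwargs)
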