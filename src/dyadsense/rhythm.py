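"""15-minute behavioral-rhythm grids and hourly coding.

Each participant-day is laid out as 96 fifteen-minute bins per sensor
channel, with missing bins preserved, so that behavioral rhythms can be
compared day by day across sensors that are not sampled simultaneously.
Hour-level codes are then derived with presence rules:

* proximity — ``together`` if any scan in the hour detected the infant's
  beacon; ``apart`` if scans completed but none detected it; ``no_data``
  when no scan ran.
* activity — ``active`` if any reading in the hour is a non-still label
  (walking, running, in_vehicle, cycling); ``inactive`` when only stillness
  was observed; ``unknown`` labels carry no evidence either way.
* speech — ``speech`` if any audio clip in the hour carries a qualifying
  speech-class label; ``no_speech`` when clips exist but none qualify;
  ``no_data`` when no clip was captured.

The day's speech-count percentage is the share of captured clips with a
qualifying speech label, a coarse proxy for social interaction around the
mother.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time
from typing import Iterable, Sequence

import pandas as pd

from .ebm_io import (
    ActivityReading,
    AudioClipPrediction,
    GpsFix,
    ParticipantStore,
    ProximityReading,
)

__all__ = [
    "CHANNELS",
    "BINS_PER_DAY",
    "BINS_PER_HOUR",
    "DayGrid",
    "HourCode",
    "DailyCodes",
    "bin_index",
    "build_day_grid",
    "code_proximity_hour",
    "code_activity_hour",
    "code_speech_hour",
    "speech_percentage",
    "code_day",
    "code_day_records",
    "proximity_chart_data",
    "codes_to_frame",
    "chart_blocks",
    "DEFAULT_SPEECH_CLASSES",
    "DEFAULT_SPEECH_THRESHOLD",
    "NOT_STILL",
]

BINS_PER_DAY = 96
BINS_PER_HOUR = 4
CHANNELS = ("proximity", "activity", "speech", "gps_presence")

NOT_STILL = frozenset({"walking", "running", "in_vehicle", "cycling"})

DEFAULT_SPEECH_CLASSES = frozenset({"Speech"})
DEFAULT_SPEECH_THRESHOLD = 0.5


def bin_index(ts: datetime | time) -> int:
    """15-minute bin of a time of day: floor(minutes since midnight / 15).

    Bins are half-open; 00:00:00 maps to bin 0 and 23:59:59 to bin 95.
    """
    t = ts.time() if isinstance(ts, datetime) else ts
    return (t.hour * 60 + t.minute) // 15


@dataclass
class DayGrid:
    """One channel's 96-bin quantization of a participant-day.

    ``bins[k]`` covers ``[k*15min, (k+1)*15min)`` from local midnight and is
    ``None`` when no record fell in the bin.  Observed bin values are
    channel-specific: proximity — True iff any scan detected the beacon;
    activity — frozenset of observed labels; speech — True iff any clip
    qualifies as speech; gps_presence — fix count.
    """

    participant_id: str
    date: date
    channel: str
    bins: list = field(default_factory=lambda: [None] * BINS_PER_DAY)

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if len(self.bins) != BINS_PER_DAY:
            raise ValueError(f"a day grid has exactly {BINS_PER_DAY} bins")

    @property
    def n_missing(self) -> int:
        return sum(1 for b in self.bins if b is None)

    def hour_bins(self, hour: int) -> list:
        return self.bins[hour * BINS_PER_HOUR : (hour + 1) * BINS_PER_HOUR]


def _qualifies_speech(
    clip: AudioClipPrediction, classes: frozenset[str], threshold: float
) -> bool:
    return any(cls in classes and score >= threshold for cls, score in clip.labels)


def build_day_grid(
    records: Iterable,
    day: date,
    channel: str,
    *,
    participant_id: str | None = None,
    speech_classes: frozenset[str] = DEFAULT_SPEECH_CLASSES,
    speech_threshold: float = DEFAULT_SPEECH_THRESHOLD,
) -> DayGrid:
    """Quantize one channel's records for ``day`` onto the 96-bin grid.

    Records from other dates are ignored; bins receiving no record stay
    missing (``None``).
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    records = [r for r in records if r.timestamp.date() == day]
    if participant_id is None:
        participant_id = records[0].participant_id if records else "SS?"
    bins: list = [None] * BINS_PER_DAY
    for rec in records:
        k = bin_index(rec.timestamp)
        if channel == "proximity":
            bins[k] = bool(bins[k]) or rec.detected
        elif channel == "activity":
            cur = bins[k] if bins[k] is not None else frozenset()
            bins[k] = cur | {rec.label}
        elif channel == "speech":
            bins[k] = bool(bins[k]) or _qualifies_speech(rec, speech_classes, speech_threshold)
        else:  # gps_presence
            bins[k] = (bins[k] or 0) + 1
    return DayGrid(participant_id, day, channel, bins)


# ---------------------------------------------------------------------------
# Hour coders
# ---------------------------------------------------------------------------


def _check_hour(bins: Sequence) -> None:
    if len(bins) != BINS_PER_HOUR:
        raise ValueError(f"an hour holds exactly {BINS_PER_HOUR} bins, got {len(bins)}")


def code_proximity_hour(bins: Sequence) -> str:
    """together / apart / no_data for one hour of proximity bins."""
    _check_hour(bins)
    observed = [b for b in bins if b is not None]
    if any(observed):
        return "together"
    if observed:
        return "apart"
    return "no_data"


def code_activity_hour(bins: Sequence) -> str:
    """active / inactive / no_data for one hour of activity-label bins.

    ``unknown`` labels are treated as missing evidence, not as stillness.
    """
    _check_hour(bins)
    labels: set[str] = set()
    for b in bins:
        if b is not None:
            labels |= b
    labels.discard("unknown")
    if labels & NOT_STILL:
        return "active"
    if labels:
        return "inactive"
    return "no_data"


def code_speech_hour(bins: Sequence) -> str:
    """speech / no_speech / no_data for one hour of audio bins."""
    _check_hour(bins)
    observed = [b for b in bins if b is not None]
    if any(observed):
        return "speech"
    if observed:
        return "no_speech"
    return "no_data"


def speech_percentage(
    clips: Iterable[AudioClipPrediction],
    *,
    speech_classes: frozenset[str] = DEFAULT_SPEECH_CLASSES,
    speech_threshold: float = DEFAULT_SPEECH_THRESHOLD,
) -> float | None:
    """Percent of a day's clips with a qualifying speech label; None if no clips."""
    clips = list(clips)
    if not clips:
        return None
    n_speech = sum(
        1 for c in clips if _qualifies_speech(c, speech_classes, speech_threshold)
    )
    return 100.0 * n_speech / len(clips)


# ---------------------------------------------------------------------------
# Daily codes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HourCode:
    hour: int
    proximity: str
    activity: str
    speech: str


@dataclass
class DailyCodes:
    participant_id: str
    date: date
    hours: list[HourCode]
    speech_pct: float | None = None

    def counts(self, channel: str) -> dict[str, int]:
        out: dict[str, int] = {}
        for h in self.hours:
            state = getattr(h, channel)
            out[state] = out.get(state, 0) + 1
        return out


def code_day_records(
    proximity: Iterable[ProximityReading],
    activity: Iterable[ActivityReading],
    audio: Iterable[AudioClipPrediction],
    participant_id: str,
    day: date,
    *,
    speech_classes: frozenset[str] = DEFAULT_SPEECH_CLASSES,
    speech_threshold: float = DEFAULT_SPEECH_THRESHOLD,
) -> DailyCodes:
    """Code one day straight from record collections (no store needed)."""
    kw = dict(
        participant_id=participant_id,
        speech_classes=speech_classes,
        speech_threshold=speech_threshold,
    )
    prox_grid = build_day_grid(proximity, day, "proximity", **kw)
    act_grid = build_day_grid(activity, day, "activity", **kw)
    speech_grid = build_day_grid(audio, day, "speech", **kw)
    hours = [
        HourCode(
            h,
            code_proximity_hour(prox_grid.hour_bins(h)),
            code_activity_hour(act_grid.hour_bins(h)),
            code_speech_hour(speech_grid.hour_bins(h)),
        )
        for h in range(24)
    ]
    day_clips = [c for c in audio if c.clip_start.date() == day]
    pct = speech_percentage(
        day_clips, speech_classes=speech_classes, speech_threshold=speech_threshold
    )
    return DailyCodes(participant_id, day, hours, pct)


def code_day(
    store: ParticipantStore,
    day: date,
    *,
    speech_classes: frozenset[str] = DEFAULT_SPEECH_CLASSES,
    speech_threshold: float = DEFAULT_SPEECH_THRESHOLD,
) -> DailyCodes:
    """Code one participant-day from an ingested store.

    An empty day yields 24 all-``no_data`` hours and a missing speech
    percentage.
    """
    return code_day_records(
        store.tables["proximity"],
        store.tables["activity"],
        store.tables["audio"],
        store.participant_id,
        day,
        speech_classes=speech_classes,
        speech_threshold=speech_threshold,
    )


def proximity_chart_data(codes: DailyCodes) -> tuple[int, int, int]:
    """(together_hours, apart_hours, no_data_hours); always sums to 24."""
    c = codes.counts("proximity")
    return (c.get("together", 0), c.get("apart", 0), c.get("no_data", 0))


def codes_to_frame(all_codes: Iterable[DailyCodes]) -> pd.DataFrame:
    """Tidy export: one row per (participant, date, hour)."""
    rows = [
        {
            "participant_id": dc.participant_id,
            "date": dc.date.isoformat(),
            "hour": h.hour,
            "proximity": h.proximity,
            "activity": h.activity,
            "speech": h.speech,
        }
        for dc in all_codes
        for h in dc.hours
    ]
    return pd.DataFrame(
        rows, columns=["participant_id", "date", "hour", "proximity", "activity", "speech"]
    )


def chart_blocks(codes: DailyCodes) -> dict:
    """Chart-ready summary of one coded day for the counselor views."""
    together, apart, no_data = proximity_chart_data(codes)
    return {
        "proximity_chart": {"together": together, "apart": apart, "no_data": no_data},
        "activity_chart": [h.activity for h in codes.hours],
        "speech_hours": [h.speech for h in codes.hours],
        "speech_pct": codes.speech_pct,
    }
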