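"""Independent brute-force oracles and randomized-scenario helpers.

The coding oracle here deliberately bypasses the 96-bin grid: it scans the
raw records hour by hour and applies the presence rules directly, so a grid
bug cannot hide in both routes.
"""

from __future__ import annotations

from datetime import date, time
from typing import Iterable

import numpy as np

from dyadsense.ebm_io import ActivityReading, AudioClipPrediction, ProximityReading
from dyadsense.synth import ActivityBout, Episode, ScheduleConfig, SpeechEpisode, Trip

NOT_STILL = {"walking", "running", "in_vehicle", "cycling"}


def brute_proximity_hour(readings: Iterable[ProximityReading], day: date, hour: int) -> str:
    in_hour = [r for r in readings if r.timestamp.date() == day and r.timestamp.hour == hour]
    if any(r.detected for r in in_hour):
        return "together"
    if in_hour:
        return "apart"
    return "no_data"


def brute_activity_hour(readings: Iterable[ActivityReading], day: date, hour: int) -> str:
    labels = {
        r.label
        for r in readings
        if r.timestamp.date() == day and r.timestamp.hour == hour and r.label != "unknown"
    }
    if labels & NOT_STILL:
        return "active"
    if labels:
        return "inactive"
    return "no_data"


def brute_speech_hour(
    clips: Iterable[AudioClipPrediction],
    day: date,
    hour: int,
    classes={"Speech"},
    threshold=0.5,
) -> str:
    in_hour = [c for c in clips if c.clip_start.date() == day and c.clip_start.hour == hour]
    if any(
        any(cls in classes and s >= threshold for cls, s in c.labels) for c in in_hour
    ):
        return "speech"
    if in_hour:
        return "no_speech"
    return "no_data"


def brute_code_day(prox, act, audio, day: date):
    """(proximity, activity, speech) hour labels, straight from raw records."""
    return (
        [brute_proximity_hour(prox, day, h) for h in range(24)],
        [brute_activity_hour(act, day, h) for h in range(24)],
        [brute_speech_hour(audio, day, h) for h in range(24)],
    )


def _rand_episode(rng: np.random.Generator, cls=Episode, **extra):
    start = int(rng.integers(0, 1430))
    end = int(rng.integers(start + 1, 1440))
    return cls(time(start // 60, start % 60), time(end // 60, end % 60), **extra)


def random_config(rng: np.random.Generator, *, aligned: bool = False) -> ScheduleConfig:
    """A randomized daily routine; ``aligned=True`` snaps all episode
    boundaries to whole hours and makes speech episodes deterministic, the
    regime under which dropout can only erase evidence, never flip it."""

    def hours_ep(cls, **extra):
        s = int(rng.integers(0, 23))
        e = int(rng.integers(s + 1, 24))
        return cls(time(s, 0), time(e if e < 24 else 23, 0 if e < 24 else 59), **extra)

    if aligned:
        seps = [hours_ep(Episode) for _ in range(int(rng.integers(0, 3)))]
        bouts = [
            hours_ep(ActivityBout, label=str(rng.choice(["walking", "running", "cycling"])))
            for _ in range(int(rng.integers(0, 3)))
        ]
        speech = [hours_ep(SpeechEpisode, probability=1.0) for _ in range(int(rng.integers(0, 3)))]
        trips = [hours_ep(Trip, offset_m=float(rng.uniform(300, 3000))) for _ in range(int(rng.integers(0, 2)))]
        interval = 15
    else:
        seps = [_rand_episode(rng) for _ in range(int(rng.integers(0, 3)))]
        bouts = [
            _rand_episode(rng, ActivityBout, label=str(rng.choice(["walking", "running", "cycling", "still"])))
            for _ in range(int(rng.integers(0, 3)))
        ]
        speech = [
            _rand_episode(rng, SpeechEpisode, probability=float(rng.uniform(0.2, 1.0)))
            for _ in range(int(rng.integers(0, 3)))
        ]
        trips = [_rand_episode(rng, Trip, offset_m=float(rng.uniform(300, 3000)))]
        interval = int(rng.choice([5, 10, 15, 30]))
    return ScheduleConfig(
        seed=int(rng.integers(0, 2**31 - 1)),
        sampling_interval_min=interval,
        separations=seps,
        activity_bouts=bouts,
        speech_episodes=speech,
        trips=trips,
        dropout=float(rng.choice([0.0, 0.2, 0.5])) if not aligned else 0.0,
    )
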