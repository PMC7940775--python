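"""Behavioral-activation award rules and weekly goals.

Awards are motivational messages triggered when a coded behavioral goal is
met — e.g. speech was present in the mother's environment during the day, or
she left home at least once.  Rules are declarative predicates over the
daily codes and mobility features; the shipped defaults cover the social
interaction, daily routine and self-care goal categories, with all
thresholds configurable via a YAML rules file.

A week-window rule is met when at least ``min_days`` days of the week
individually satisfy the day-level predicate (default 1), which is how a
weekly goal such as "have a speech day this week" is expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date
from typing import Iterable, Mapping, Sequence

import yaml

from .mobility import MobilityFeatures
from .rhythm import DailyCodes

__all__ = [
    "AwardRule",
    "Award",
    "WeeklyGoal",
    "DEFAULT_RULES",
    "evaluate_rules",
    "merge_awards",
    "goal_progress",
    "load_rules",
    "dump_rules",
]

_CHANNELS = ("proximity", "activity", "speech", "mobility")
_STATISTICS = ("hours_in_state", "speech_pct", "fraction_outside")
_STAT_CHANNELS = {
    "hours_in_state": ("proximity", "activity", "speech"),
    "speech_pct": ("speech",),
    "fraction_outside": ("mobility",),
}
_COMPARATORS = (">=", "<=")


@dataclass(frozen=True)
class AwardRule:
    """Declarative predicate over one participant-day (or week) of codes."""

    rule_id: str
    description: str
    channel: str
    statistic: str
    threshold: float
    state: str | None = None
    comparator: str = ">="
    window: str = "day"
    min_days: int = 1

    def __post_init__(self) -> None:
        if self.channel not in _CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.statistic not in _STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.channel not in _STAT_CHANNELS[self.statistic]:
            raise ValueError(
                f"statistic {self.statistic!r} is not defined for channel {self.channel!r}"
            )
        if self.comparator not in _COMPARATORS:
            raise ValueError(f"comparator must be one of {_COMPARATORS}")
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        if self.window not in ("day", "week"):
            raise ValueError("window must be 'day' or 'week'")
        if self.statistic == "hours_in_state" and not self.state:
            raise ValueError("hours_in_state rules need a state")

    def day_statistic(
        self, codes: DailyCodes | None, mob: MobilityFeatures | None
    ) -> float | None:
        if self.statistic == "hours_in_state":
            if codes is None:
                return None
            return float(codes.counts(self.channel).get(self.state, 0))
        if self.statistic == "speech_pct":
            return None if codes is None else codes.speech_pct
        # fraction_outside
        return None if mob is None else mob.fraction_time_outside_home

    def day_satisfied(
        self, codes: DailyCodes | None, mob: MobilityFeatures | None
    ) -> bool:
        value = self.day_statistic(codes, mob)
        if value is None:
            return False
        return value >= self.threshold if self.comparator == ">=" else value <= self.threshold


@dataclass(frozen=True)
class Award:
    """One granted award; unique per (participant, rule, period)."""

    participant_id: str
    rule_id: str
    period: str  # ISO date for day rules, "<start>/<end>" for week rules
    message: str

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.participant_id, self.rule_id, self.period)


@dataclass(frozen=True)
class WeeklyGoal:
    """A goal the mother set in session, optionally linked to a rule."""

    participant_id: str
    week_index: int
    text: str
    rule_id: str | None = None
    status: str = "set"

    def __post_init__(self) -> None:
        if self.status not in ("set", "met", "unmet"):
            raise ValueError(f"bad status {self.status!r}")


#: message templates keyed by rule_id; placeholder content, not study cards
MESSAGE_CATALOG = {
    "speech_day": "Great job! There were conversations around you today.",
    "active_day": "Well done staying active today!",
    "together_day": "Lovely — you and your baby spent many hours together today.",
    "left_home_day": "Nice! You got out of the house today.",
}
_FALLBACK_MESSAGE = "Goal '{rule_id}' achieved — keep it up!"


def _message_for(rule: AwardRule) -> str:
    return MESSAGE_CATALOG.get(rule.rule_id, _FALLBACK_MESSAGE.format(rule_id=rule.rule_id))


DEFAULT_RULES: tuple[AwardRule, ...] = (
    AwardRule(
        "speech_day",
        "speech present in the environment at some hour of the day",
        channel="speech",
        statistic="hours_in_state",
        state="speech",
        threshold=1,
    ),
    AwardRule(
        "active_day",
        "physically active during at least 4 hours of the day",
        channel="activity",
        statistic="hours_in_state",
        state="active",
        threshold=4,
    ),
    AwardRule(
        "together_day",
        "together with the infant during at least 8 hours of the day",
        channel="proximity",
        statistic="hours_in_state",
        state="together",
        threshold=8,
    ),
    AwardRule(
        "left_home_day",
        "spent some observed time outside the home",
        channel="mobility",
        statistic="fraction_outside",
        threshold=0.01,
    ),
)


def evaluate_rules(
    codes_by_date: Mapping[date, DailyCodes],
    mobility_by_date: Mapping[date, MobilityFeatures | None],
    rules: Sequence[AwardRule] = DEFAULT_RULES,
    *,
    participant_id: str | None = None,
    warnings: list[str] | None = None,
) -> list[Award]:
    """Evaluate rules over a period of coded days; one award per satisfied
    (rule, period), in deterministic (date, rule_id) order.

    Day-window rules grant per qualifying day; week-window rules grant once
    over the whole supplied period.  The function is pure, so re-evaluating
    an identical period reproduces the identical award list.
    """
    days = sorted(codes_by_date)
    if participant_id is None:
        participant_id = next(iter(codes_by_date.values())).participant_id if days else "SS?"
    awards: list[Award] = []
    day_rules = sorted((r for r in rules if r.window == "day"), key=lambda r: r.rule_id)
    week_rules = sorted((r for r in rules if r.window == "week"), key=lambda r: r.rule_id)
    for d in days:
        codes = codes_by_date.get(d)
        mob = mobility_by_date.get(d)
        for rule in day_rules:
            if rule.channel == "mobility" and mob is None and warnings is not None:
                warnings.append(f"{d}: rule {rule.rule_id} skipped (no mobility features)")
            if rule.day_satisfied(codes, mob):
                awards.append(
                    Award(participant_id, rule.rule_id, d.isoformat(), _message_for(rule))
                )
    if days:
        period = f"{days[0].isoformat()}/{days[-1].isoformat()}"
        for rule in week_rules:
            n_met = sum(
                1
                for d in days
                if rule.day_satisfied(codes_by_date.get(d), mobility_by_date.get(d))
            )
            if n_met >= rule.min_days:
                awards.append(Award(participant_id, rule.rule_id, period, _message_for(rule)))
    return awards


def merge_awards(existing: Iterable[Award], new: Iterable[Award]) -> list[Award]:
    """Union of award logs with duplicates (same participant/rule/period) dropped."""
    seen = set()
    merged: list[Award] = []
    for a in list(existing) + list(new):
        if a.key in seen:
            continue
        seen.add(a.key)
        merged.append(a)
    merged.sort(key=lambda a: (a.period, a.rule_id, a.participant_id))
    return merged


def goal_progress(
    goal: WeeklyGoal,
    codes_by_date: Mapping[date, DailyCodes],
    mobility_by_date: Mapping[date, MobilityFeatures | None],
    rules_by_id: Mapping[str, AwardRule],
) -> WeeklyGoal:
    """Resolve a weekly goal's status from the week's coded days.

    Unlinked free-text goals keep their current status.  A linked goal is
    ``met`` iff its rule (evaluated over the week window) is satisfied.
    """
    if goal.rule_id is None or goal.rule_id not in rules_by_id:
        return goal
    rule = rules_by_id[goal.rule_id]
    days = sorted(codes_by_date)
    if rule.window == "week":
        n_met = sum(
            1
            for d in days
            if rule.day_satisfied(codes_by_date.get(d), mobility_by_date.get(d))
        )
        met = n_met >= rule.min_days
    else:
        # a day rule linked to a weekly goal: met if any day of the week qualifies
        met = any(
            rule.day_satisfied(codes_by_date.get(d), mobility_by_date.get(d)) for d in days
        )
    return replace(goal, status="met" if met else "unmet")


# ---------------------------------------------------------------------------
# Rules config I/O
# ---------------------------------------------------------------------------


def load_rules(path) -> list[AwardRule]:
    """Load award rules from a YAML file (a list of rule mappings)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValueError("rules file must contain a list of rules")
    return [AwardRule(**entry) for entry in raw]


def dump_rules(rules: Sequence[AwardRule], path) -> None:
    entries = [
        {
            "rule_id": r.rule_id,
            "description": r.description,
            "channel": r.channel,
            "statistic": r.statistic,
            "threshold": r.threshold,
            "state": r.state,
            "comparator": r.comparator,
            "window": r.window,
            "min_days": r.min_days,
        }
        for r in rules
    ]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)
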