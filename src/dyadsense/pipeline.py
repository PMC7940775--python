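"""End-to-end weekly workflow: ingest → code → mobility → awards → report.

Mirrors the counselor's weekly preparation: load the week's uploaded sensor
files from a local inbound folder, code each day's behavioral rhythms,
derive mobility features, evaluate award rules, and assemble an offline
report with chart-ready data blocks and a per-sensor data-completeness
summary.  Everything operates on local folders only — no network anywhere.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import ebm_io, mobility as mob, rhythm
from .awards import Award, AwardRule, DEFAULT_RULES, WeeklyGoal, evaluate_rules, goal_progress
from .ebm_io import ParticipantStore
from .mobility import HomeEstimate, MobilityFeatures
from .rhythm import DailyCodes

__all__ = ["WeekReport", "ParticipantNotFoundError", "run_week", "export_report"]

log = logging.getLogger("dyadsense")


class ParticipantNotFoundError(KeyError):
    """Requested participant has no data in the inbound folder."""


@dataclass
class WeekReport:
    """Everything a counselor needs for one participant-week."""

    participant_id: str
    week_start: date
    days: list[date]
    codes: dict[date, DailyCodes]
    features: dict[date, MobilityFeatures]
    home: HomeEstimate | None
    charts: dict[date, dict]
    awards: list[Award]
    goals: list[WeeklyGoal] = field(default_factory=list)
    completeness: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "week_start": self.week_start.isoformat(),
            "days": [d.isoformat() for d in self.days],
            "home": None
            if self.home is None
            else {"lat": self.home.lat, "lon": self.home.lon, "support": self.home.support},
            "codes": {
                d.isoformat(): {
                    "hours": [
                        {"hour": h.hour, "proximity": h.proximity, "activity": h.activity, "speech": h.speech}
                        for h in dc.hours
                    ],
                    "speech_pct": dc.speech_pct,
                }
                for d, dc in self.codes.items()
            },
            "mobility": {
                d.isoformat(): {
                    "n_fixes": f.n_fixes,
                    "radius_of_movement_m": f.radius_of_movement_m,
                    "farthest_distance_from_home_m": f.farthest_distance_from_home_m,
                    "fraction_time_outside_home": f.fraction_time_outside_home,
                }
                for d, f in self.features.items()
            },
            "charts": {d.isoformat(): block for d, block in self.charts.items()},
            "awards": [
                {"participant_id": a.participant_id, "rule_id": a.rule_id, "period": a.period, "message": a.message}
                for a in self.awards
            ],
            "goals": [
                {"week_index": g.week_index, "text": g.text, "rule_id": g.rule_id, "status": g.status}
                for g in self.goals
            ],
            "completeness_pct": self.completeness,
            "warnings": self.warnings,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def _completeness(
    codes: dict[date, DailyCodes], store: ParticipantStore, days: Sequence[date]
) -> dict[str, float]:
    """Percent of the window's hours with any observation, per sensor."""
    n_hours = 24 * len(days)
    out: dict[str, float] = {}
    for channel in ("proximity", "activity", "speech"):
        observed = sum(
            1
            for d in days
            for h in codes[d].hours
            if getattr(h, channel) != "no_data"
        )
        out[channel] = 100.0 * observed / n_hours if n_hours else 0.0
    gps_hours = {
        (f.timestamp.date(), f.timestamp.hour)
        for f in store.tables["gps"]
        if f.timestamp.date() in set(days)
    }
    out["gps"] = 100.0 * len(gps_hours) / n_hours if n_hours else 0.0
    return out


def run_week(
    inbound: str | Path,
    participant_id: str,
    week_start: date,
    *,
    n_days: int = 7,
    rules: Sequence[AwardRule] = DEFAULT_RULES,
    goals: Sequence[WeeklyGoal] = (),
    stores: dict[str, ParticipantStore] | None = None,
    speech_classes=rhythm.DEFAULT_SPEECH_CLASSES,
    speech_threshold: float = rhythm.DEFAULT_SPEECH_THRESHOLD,
    home_radius_m: float = mob.DEFAULT_HOME_RADIUS_M,
) -> WeekReport:
    """Build the weekly report for one participant from an inbound folder.

    Raises :class:`ParticipantNotFoundError` when the participant has no
    store after ingest; a participant present but without records in the
    window yields an all-``no_data`` report with a warning.
    """
    stores, ingest_report = ebm_io.scan_inbound(inbound, stores)
    log.info(
        "ingest: %d files loaded, %d unparsed, %d rows skipped",
        ingest_report.files_loaded,
        len(ingest_report.files_unparsed),
        ingest_report.rows_skipped,
    )
    if participant_id not in stores:
        raise ParticipantNotFoundError(participant_id)
    store = stores[participant_id]
    days = [week_start + timedelta(days=i) for i in range(n_days)]
    warnings: list[str] = []
    if ingest_report.files_unparsed:
        warnings.append(f"unparsed files skipped: {ingest_report.files_unparsed}")

    codes = {
        d: rhythm.code_day(
            store, d, speech_classes=speech_classes, speech_threshold=speech_threshold
        )
        for d in days
    }
    home = mob.estimate_home(store.tables["gps"])
    features = {
        d: mob.mobility_features(
            store.records_for_day("gps", d), home, d, home_radius_m=home_radius_m
        )
        for d in days
    }
    charts = {d: rhythm.chart_blocks(codes[d]) for d in days}
    for d in days:
        day_fixes = store.records_for_day("gps", d)
        if day_fixes:
            grid = mob.build_heatmap(day_fixes)
            charts[d]["heatmap"] = {
                "cell_size": grid.cell_size,
                "bbox": [grid.min_lat, grid.min_lon, grid.max_lat, grid.max_lon],
                "counts": grid.counts.tolist(),
            }
        else:
            charts[d]["heatmap"] = None

    if all(
        all(h.proximity == "no_data" and h.activity == "no_data" and h.speech == "no_data" for h in codes[d].hours)
        for d in days
    ):
        warnings.append("no sensor data in the requested window")
        log.warning("participant %s: empty week starting %s", participant_id, week_start)

    award_warnings: list[str] = []
    granted = evaluate_rules(
        codes, features, rules, participant_id=participant_id, warnings=award_warnings
    )
    warnings.extend(award_warnings)
    rules_by_id = {r.rule_id: r for r in rules}
    resolved_goals = [goal_progress(g, codes, features, rules_by_id) for g in goals]

    report = WeekReport(
        participant_id=participant_id,
        week_start=week_start,
        days=days,
        codes=codes,
        features=features,
        home=home,
        charts=charts,
        awards=granted,
        goals=resolved_goals,
        completeness=_completeness(codes, store, days),
        warnings=warnings,
    )
    for a in granted:
        log.info("award: %s %s %s", a.participant_id, a.rule_id, a.period)
    return report


def export_report(
    report: WeekReport,
    out_dir: str | Path,
    *,
    render_charts: bool = False,
) -> list[Path]:
    """Write the report as JSON plus tidy delimited tables (and optional PNGs).

    Exports are byte-stable: rerunning on identical inputs reproduces
    identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    path = out_dir / "report.json"
    path.write_text(report.to_json() + "\n", encoding="utf-8")
    written.append(path)

    path = out_dir / "codes.csv"
    rhythm.codes_to_frame(report.codes.values()).to_csv(path, index=False)
    written.append(path)

    mob_rows = [
        {
            "participant_id": report.participant_id,
            "date": d.isoformat(),
            "n_fixes": f.n_fixes,
            "radius_of_movement_m": f.radius_of_movement_m,
            "farthest_distance_from_home_m": f.farthest_distance_from_home_m,
            "fraction_time_outside_home": f.fraction_time_outside_home,
        }
        for d, f in sorted(report.features.items())
    ]
    path = out_dir / "mobility.csv"
    pd.DataFrame(
        mob_rows,
        columns=[
            "participant_id",
            "date",
            "n_fixes",
            "radius_of_movement_m",
            "farthest_distance_from_home_m",
            "fraction_time_outside_home",
        ],
    ).to_csv(path, index=False)
    written.append(path)

    award_rows = [
        {"participant_id": a.participant_id, "rule_id": a.rule_id, "period": a.period, "message": a.message}
        for a in report.awards
    ]
    path = out_dir / "awards.csv"
    pd.DataFrame(
        award_rows, columns=["participant_id", "rule_id", "period", "message"]
    ).to_csv(path, index=False)
    written.append(path)

    if render_charts:
        written.extend(_render_charts(report, out_dir))
    return written


def _render_charts(report: WeekReport, out_dir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written: list[Path] = []
    days = report.days
    labels = [d.isoformat() for d in days]
    together = [report.charts[d]["proximity_chart"]["together"] for d in days]
    apart = [report.charts[d]["proximity_chart"]["apart"] for d in days]
    nodata = [report.charts[d]["proximity_chart"]["no_data"] for d in days]

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(labels, together, label="together")
    ax.bar(labels, apart, bottom=together, label="apart")
    ax.bar(labels, nodata, bottom=[t + a for t, a in zip(together, apart)], label="no data")
    ax.set_ylabel("hours")
    ax.set_title(f"{report.participant_id} — mother–infant proximity")
    ax.legend()
    fig.autofmt_xdate()
    path = out_dir / "proximity_chart.png"
    fig.savefig(path, dpi=100)
    plt.close(fig)
    written.append(path)

    state_level = {"active": 1, "inactive": 0, "no_data": float("nan")}
    fig, ax = plt.subplots(figsize=(8, 4))
    for d in days:
        levels = [state_level[s] for s in report.charts[d]["activity_chart"]]
        ax.plot(range(24), levels, marker="o", label=d.isoformat())
    ax.set_xlabel("hour of day")
    ax.set_yticks([0, 1], ["inactive", "active"])
    ax.set_title(f"{report.participant_id} — hourly activity")
    ax.legend(fontsize="x-small")
    path = out_dir / "activity_chart.png"
    fig.savefig(path, dpi=100)
    plt.close(fig)
    written.append(path)

    for d in days:
        block = report.charts[d]["heatmap"]
        if block is None:
            continue
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.imshow(block["counts"], origin="lower", cmap="hot")
        ax.set_title(f"{report.participant_id} {d.isoformat()} — GPS heat map")
        path = out_dir / f"heatmap_{d.isoformat()}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written
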