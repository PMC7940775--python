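"""File conventions, record schemas, and inbound-folder ingest.

Passive-sensing collector apps in this pipeline emit one delimited-text file
per participant, sensor and day, named ``<ID>-<TYPE>_<YYYYMMDD>.<ext>`` (raw
audio clips additionally carry a clip time, ``<ID>-EAR_<YYYYMMDDHHMMSS>.m4a``;
the weekly audio-prediction table is dateless, ``<ID>-AUDIO.csv``).  This
module parses and emits those names and schemas, and loads an inbound folder
into per-participant stores mirroring the platform's four logical tables
(gps, proximity, activity, audio).

All timestamps are naive local datetimes: the analysis reasons in the
participant's local daily schedule, never in UTC.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from datetime import date, datetime, time
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Datatype",
    "FileMeta",
    "GpsFix",
    "ProximityReading",
    "ActivityReading",
    "AudioClipPrediction",
    "ParticipantStore",
    "ParseReport",
    "IngestReport",
    "FilenameParseError",
    "UnsupportedDatatypeError",
    "CorruptFileError",
    "parse_filename",
    "make_filename",
    "read_sensor_file",
    "write_sensor_file",
    "scan_inbound",
    "ACTIVITY_LABELS",
]

DATATYPES = ("GPS", "PROXIMITY", "ACTIVITY", "EAR", "AUDIO")
Datatype = str  # one of DATATYPES

ACTIVITY_LABELS = frozenset(
    {"still", "walking", "running", "in_vehicle", "cycling", "unknown"}
)

#: day-file datatypes (one file per participant-day, date token required)
_DAY_TYPES = ("GPS", "PROXIMITY", "ACTIVITY")

_NAME_RE = re.compile(
    r"^(?P<pid>SS[A-Z0-9]+)-(?P<dtype>[A-Z]+)(?:_(?P<stamp>\d+))?\.(?P<ext>[A-Za-z0-9]+)$"
)


class FilenameParseError(ValueError):
    """Filename does not follow the ``<ID>-<TYPE>_<DATE>.<ext>`` convention."""


class UnsupportedDatatypeError(FilenameParseError):
    """Filename parses but names a datatype outside the supported set."""


class CorruptFileError(ValueError):
    """More than half of a sensor file's data rows failed schema validation."""


@dataclass(frozen=True)
class FileMeta:
    """Parsed identity of one collector file."""

    participant_id: str
    datatype: Datatype
    date: date | None = None
    clip_time: time | None = None
    extension: str = "txt"

    def __post_init__(self) -> None:
        if not self.participant_id or not self.participant_id.startswith("SS"):
            raise ValueError(f"participant_id must start with 'SS': {self.participant_id!r}")
        if self.participant_id != self.participant_id.upper():
            raise ValueError(f"participant_id must be uppercase: {self.participant_id!r}")
        if self.datatype not in DATATYPES:
            raise ValueError(f"unknown datatype {self.datatype!r}")
        if self.datatype == "AUDIO" and self.date is not None:
            raise ValueError("weekly AUDIO files carry no date")
        if self.datatype != "EAR" and self.clip_time is not None:
            raise ValueError("clip_time is only valid for EAR clips")
        if self.datatype == "EAR" and self.clip_time is None:
            raise ValueError("EAR clips must carry a clip_time")


def parse_filename(name: str) -> FileMeta:
    """Parse a bare collector filename into its :class:`FileMeta`.

    >>> parse_filename("SSXXXX-PROXIMITY_20190605.txt").date
    datetime.date(2019, 6, 5)
    """
    if "/" in name or "\\" in name:
        raise FilenameParseError(f"expected a bare filename, got a path: {name!r}")
    m = _NAME_RE.match(name)
    if m is None:
        raise FilenameParseError(
            f"filename {name!r} does not match '<ID>-<TYPE>_<YYYYMMDD>.<ext>'"
        )
    pid, dtype, stamp, ext = m.group("pid", "dtype", "stamp", "ext")
    if dtype not in DATATYPES:
        raise UnsupportedDatatypeError(f"unsupported datatype token {dtype!r} in {name!r}")
    if dtype == "AUDIO":
        if stamp is not None:
            raise FilenameParseError(f"weekly AUDIO files carry no date: {name!r}")
        return FileMeta(pid, dtype, None, None, ext)
    if stamp is None:
        raise FilenameParseError(f"missing date token in {name!r}")
    if dtype == "EAR":
        if len(stamp) != 14:
            raise FilenameParseError(f"EAR date token must be YYYYMMDDHHMMSS: {stamp!r}")
        try:
            dt = datetime.strptime(stamp, "%Y%m%d%H%M%S")
        except ValueError as exc:
            raise FilenameParseError(f"bad EAR timestamp {stamp!r}: {exc}") from exc
        return FileMeta(pid, dtype, dt.date(), dt.time(), ext)
    if len(stamp) != 8:
        raise FilenameParseError(f"date token must be YYYYMMDD: {stamp!r}")
    try:
        d = datetime.strptime(stamp, "%Y%m%d").date()
    except ValueError as exc:
        raise FilenameParseError(f"bad date token {stamp!r}: {exc}") from exc
    return FileMeta(pid, dtype, d, None, ext)


def make_filename(meta: FileMeta) -> str:
    """Inverse of :func:`parse_filename` on valid metas."""
    if meta.datatype == "AUDIO":
        return f"{meta.participant_id}-AUDIO.{meta.extension}"
    if meta.datatype == "EAR":
        stamp = datetime.combine(meta.date, meta.clip_time).strftime("%Y%m%d%H%M%S")
    else:
        stamp = meta.date.strftime("%Y%m%d")
    return f"{meta.participant_id}-{meta.datatype}_{stamp}.{meta.extension}"


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GpsFix:
    participant_id: str
    timestamp: datetime
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of bounds: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude out of bounds: {self.lon}")


@dataclass(frozen=True)
class ProximityReading:
    """One completed Bluetooth scan for the infant's beacon.

    ``detected=False`` rows are completed scans that did not see the beacon;
    they are the evidence that lets an hour be coded ``apart`` rather than
    merely missing.
    """

    participant_id: str
    timestamp: datetime
    beacon_id: str
    detected: bool
    rssi: float | None = None

    def __post_init__(self) -> None:
        if not self.detected and self.rssi is not None:
            raise ValueError("rssi must be missing when the beacon was not detected")


@dataclass(frozen=True)
class ActivityReading:
    participant_id: str
    timestamp: datetime
    label: str

    def __post_init__(self) -> None:
        if self.label not in ACTIVITY_LABELS:
            raise ValueError(f"unknown activity label {self.label!r}")


@dataclass(frozen=True)
class AudioClipPrediction:
    """Classifier output for one ~30-second ambient audio clip.

    ``labels`` holds (sound_class, score) pairs; an empty tuple is a clip for
    which the classifier emitted no label (a silent clip).
    """

    participant_id: str
    clip_start: datetime
    duration: float = 30.0
    labels: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("clip duration must be positive")
        for cls, score in self.labels:
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"score out of [0,1] for {cls!r}: {score}")

    @property
    def timestamp(self) -> datetime:  # uniform access across record types
        return self.clip_start


SensorRecord = GpsFix | ProximityReading | ActivityReading | AudioClipPrediction

_RECORD_TYPE = {
    "GPS": GpsFix,
    "PROXIMITY": ProximityReading,
    "ACTIVITY": ActivityReading,
    "AUDIO": AudioClipPrediction,
}
_TYPE_OF_RECORD = {v: k for k, v in _RECORD_TYPE.items()}

_HEADERS = {
    "GPS": ["timestamp", "lat", "lon"],
    "PROXIMITY": ["timestamp", "beacon_id", "detected", "rssi"],
    "ACTIVITY": ["timestamp", "label"],
    "AUDIO": ["clip_start", "duration", "label", "score"],
}

_TS_FMT = "%Y-%m-%dT%H:%M:%S"


@dataclass
class ParseReport:
    """Per-file accounting of rows read vs rows rejected."""

    path: str
    rows_total: int = 0
    rows_ok: int = 0
    rows_skipped: int = 0
    errors: list[str] = field(default_factory=list)


def _parse_ts(text: str) -> datetime:
    return datetime.strptime(text, _TS_FMT)


def _fmt_ts(ts: datetime) -> str:
    return ts.strftime(_TS_FMT)


def _parse_bool(text: str) -> bool:
    t = text.strip().lower()
    if t in ("true", "1"):
        return True
    if t in ("false", "0"):
        return False
    raise ValueError(f"not a boolean: {text!r}")


def read_sensor_file(path: str | Path, meta: FileMeta) -> tuple[list[SensorRecord], ParseReport]:
    """Read one sensor file into typed records, skipping malformed rows.

    Returns the records in timestamp order plus a :class:`ParseReport`
    counting skipped rows.  Raises :class:`CorruptFileError` when more than
    half of the data rows fail validation, and ``OSError`` when the file
    cannot be read.
    """
    path = Path(path)
    if meta.datatype not in _RECORD_TYPE:
        raise ValueError(f"datatype {meta.datatype!r} has no record schema")
    report = ParseReport(path=str(path))
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            return [], report
        if [h.strip() for h in header] != _HEADERS[meta.datatype]:
            raise CorruptFileError(
                f"{path}: header {header!r} does not match schema {_HEADERS[meta.datatype]}"
            )
        rows = list(reader)

    pid = meta.participant_id
    records: list[SensorRecord] = []

    if meta.datatype == "AUDIO":
        # one row per (clip, label); silent clips appear as a single row with
        # empty label and score
        clips: dict[tuple[datetime, float], list[tuple[str, float]]] = {}
        order: list[tuple[datetime, float]] = []
        for row in rows:
            report.rows_total += 1
            try:
                if len(row) != 4:
                    raise ValueError(f"expected 4 fields, got {len(row)}")
                start = _parse_ts(row[0])
                duration = float(row[1])
                if duration <= 0:
                    raise ValueError("duration must be positive")
                key = (start, duration)
                if key not in clips:
                    clips[key] = []
                    order.append(key)
                if row[2] != "":
                    score = float(row[3])
                    if not 0.0 <= score <= 1.0:
                        raise ValueError(f"score out of [0,1]: {score}")
                    clips[key].append((row[2], score))
                report.rows_ok += 1
            except (ValueError, IndexError) as exc:
                report.rows_skipped += 1
                report.errors.append(f"row {report.rows_total}: {exc}")
        records = [
            AudioClipPrediction(pid, start, duration, tuple(clips[(start, duration)]))
            for start, duration in order
        ]
    else:
        for row in rows:
            report.rows_total += 1
            try:
                if meta.datatype == "GPS":
                    if len(row) != 3:
                        raise ValueError(f"expected 3 fields, got {len(row)}")
                    rec: SensorRecord = GpsFix(pid, _parse_ts(row[0]), float(row[1]), float(row[2]))
                elif meta.datatype == "PROXIMITY":
                    if len(row) != 4:
                        raise ValueError(f"expected 4 fields, got {len(row)}")
                    rssi = None if row[3] == "" else float(row[3])
                    rec = ProximityReading(pid, _parse_ts(row[0]), row[1], _parse_bool(row[2]), rssi)
                else:  # ACTIVITY
                    if len(row) != 2:
                        raise ValueError(f"expected 2 fields, got {len(row)}")
                    rec = ActivityReading(pid, _parse_ts(row[0]), row[1])
                records.append(rec)
                report.rows_ok += 1
            except (ValueError, IndexError) as exc:
                report.rows_skipped += 1
                report.errors.append(f"row {report.rows_total}: {exc}")

    if report.rows_total > 0 and report.rows_skipped * 2 > report.rows_total:
        raise CorruptFileError(
            f"{path}: {report.rows_skipped}/{report.rows_total} rows malformed"
        )
    records.sort(key=lambda r: r.timestamp)
    return records, report


def _fmt_float(x: float) -> str:
    return repr(float(x))


def write_sensor_file(
    records: Sequence[SensorRecord],
    folder: str | Path,
    *,
    datatype: Datatype | None = None,
    participant_id: str | None = None,
    file_date: date | None = None,
    extension: str | None = None,
) -> FileMeta:
    """Write homogeneous records to a convention-named file in ``folder``.

    Day-file types (GPS/PROXIMITY/ACTIVITY) are named with their date; AUDIO
    emits the dateless weekly table.  The written file round-trips through
    :func:`read_sensor_file` field-for-field.  For an empty record list,
    ``datatype``, ``participant_id`` and (for day files) ``file_date`` must be
    given; otherwise they are inferred from the records.
    """
    folder = Path(folder)
    if records:
        dtypes = {_TYPE_OF_RECORD[type(r)] for r in records}
        pids = {r.participant_id for r in records}
        if len(dtypes) > 1:
            raise ValueError(f"mixed record datatypes: {sorted(dtypes)}")
        if len(pids) > 1:
            raise ValueError(f"mixed participants: {sorted(pids)}")
        datatype = dtypes.pop()
        participant_id = pids.pop()
        if datatype in _DAY_TYPES and file_date is None:
            dates = {r.timestamp.date() for r in records}
            if len(dates) > 1:
                raise ValueError(f"day file spans multiple dates: {sorted(dates)}")
            file_date = dates.pop()
    if datatype is None or participant_id is None:
        raise ValueError("datatype and participant_id required for empty record lists")
    if datatype in _DAY_TYPES and file_date is None:
        raise ValueError(f"{datatype} day files require a date")

    if extension is None:
        extension = "csv" if datatype == "AUDIO" else "txt"
    meta = FileMeta(
        participant_id,
        datatype,
        None if datatype == "AUDIO" else file_date,
        None,
        extension,
    )
    out = folder / make_filename(meta)
    ordered = sorted(records, key=lambda r: r.timestamp)
    with open(out, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADERS[datatype])
        for rec in ordered:
            if datatype == "GPS":
                writer.writerow([_fmt_ts(rec.timestamp), _fmt_float(rec.lat), _fmt_float(rec.lon)])
            elif datatype == "PROXIMITY":
                writer.writerow(
                    [
                        _fmt_ts(rec.timestamp),
                        rec.beacon_id,
                        "true" if rec.detected else "false",
                        "" if rec.rssi is None else _fmt_float(rec.rssi),
                    ]
                )
            elif datatype == "ACTIVITY":
                writer.writerow([_fmt_ts(rec.timestamp), rec.label])
            else:  # AUDIO
                base = [_fmt_ts(rec.clip_start), _fmt_float(rec.duration)]
                if rec.labels:
                    for cls, score in rec.labels:
                        writer.writerow(base + [cls, _fmt_float(score)])
                else:
                    writer.writerow(base + ["", ""])
    return meta


# ---------------------------------------------------------------------------
# Participant store + inbound ingest
# ---------------------------------------------------------------------------

TABLE_OF_DATATYPE = {"GPS": "gps", "PROXIMITY": "proximity", "ACTIVITY": "activity", "AUDIO": "audio"}


@dataclass
class ParticipantStore:
    """In-memory mirror of one participant's four logical sensor tables."""

    participant_id: str
    tables: dict[str, list[SensorRecord]] = field(
        default_factory=lambda: {"gps": [], "proximity": [], "activity": [], "audio": []}
    )
    provenance: list[FileMeta] = field(default_factory=list)
    _seen: set = field(default_factory=set, repr=False)

    def add_records(self, records: Iterable[SensorRecord], meta: FileMeta) -> int:
        """Add records from one file; duplicates are suppressed. Returns #added."""
        table = TABLE_OF_DATATYPE[meta.datatype]
        added = 0
        for rec in records:
            if rec.participant_id != self.participant_id:
                raise ValueError(
                    f"record participant {rec.participant_id!r} != store {self.participant_id!r}"
                )
            key = (meta.datatype, rec)
            if key in self._seen:
                continue
            self._seen.add(key)
            self.tables[table].append(rec)
            added += 1
        self.tables[table].sort(key=lambda r: r.timestamp)
        if meta not in self.provenance:
            self.provenance.append(meta)
        return added

    def records_for_day(self, table: str, d: date) -> list[SensorRecord]:
        return [r for r in self.tables[table] if r.timestamp.date() == d]

    def dates(self) -> list[date]:
        out = {r.timestamp.date() for recs in self.tables.values() for r in recs}
        return sorted(out)


@dataclass
class IngestReport:
    """Summary of one inbound-folder scan."""

    files_loaded: int = 0
    files_unparsed: list[str] = field(default_factory=list)
    files_rejected: list[str] = field(default_factory=list)
    records_added: dict[tuple[str, str], int] = field(default_factory=dict)
    file_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    rows_skipped: int = 0
    parse_reports: list[ParseReport] = field(default_factory=list)


def scan_inbound(
    folder: str | Path,
    stores: dict[str, ParticipantStore] | None = None,
    *,
    on_unknown: str = "create",
) -> tuple[dict[str, ParticipantStore], IngestReport]:
    """Ingest every convention-named file under ``folder`` into stores.

    Scanning is idempotent: rescanning the same folder adds no duplicate
    records.  ``on_unknown`` controls the policy for participant ids without
    an existing store: ``"create"`` (default) or ``"reject"``.  Files whose
    names do not parse are listed in the report, never fatal.  Raw EAR clips
    are registered in provenance only; their audio content is not decoded.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise FileNotFoundError(f"inbound folder not found: {folder}")
    if on_unknown not in ("create", "reject"):
        raise ValueError(f"on_unknown must be 'create' or 'reject', got {on_unknown!r}")
    stores = stores if stores is not None else {}
    report = IngestReport()
    for path in sorted(folder.iterdir()):
        if not path.is_file():
            continue
        try:
            meta = parse_filename(path.name)
        except FilenameParseError:
            report.files_unparsed.append(path.name)
            continue
        if meta.participant_id not in stores:
            if on_unknown == "reject":
                report.files_rejected.append(path.name)
                continue
            stores[meta.participant_id] = ParticipantStore(meta.participant_id)
        store = stores[meta.participant_id]
        if meta.datatype == "EAR":
            if meta not in store.provenance:
                store.provenance.append(meta)
            report.files_loaded += 1
            continue
        records, preport = read_sensor_file(path, meta)
        added = store.add_records(records, meta)
        key = (meta.participant_id, meta.datatype)
        report.records_added[key] = report.records_added.get(key, 0) + added
        report.file_counts[key] = report.file_counts.get(key, 0) + 1
        report.rows_skipped += preport.rows_skipped
        report.parse_reports.append(preport)
        report.files_loaded += 1
    return stores, report
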