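"""File-convention parsing, record round trips, and inbound ingest."""

from __future__ import annotations

from datetime import date, datetime, time

import pytest
from hypothesis import given, strategies as st

from dyadsense.ebm_io import (
    ActivityReading,
    AudioClipPrediction,
    CorruptFileError,
    FileMeta,
    FilenameParseError,
    GpsFix,
    ProximityReading,
    UnsupportedDatatypeError,
    make_filename,
    parse_filename,
    read_sensor_file,
    scan_inbound,
    write_sensor_file,
)

# ---------------------------------------------------------------------------
# filename grammar
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "name, pid, dtype, day",
    [
        ("SSXXXX-PROXIMITY_20190605.txt", "SSXXXX", "PROXIMITY", date(2019, 6, 5)),
        ("SSXXXX-AUDIO.csv", "SSXXXX", "AUDIO", None),
        ("SS0001-GPS_20190605.csv", "SS0001", "GPS", date(2019, 6, 5)),
        ("SS0002-ACTIVITY_20191231.txt", "SS0002", "ACTIVITY", date(2019, 12, 31)),
    ],
)
def test_parse_filename_convention(name, pid, dtype, day):
    meta = parse_filename(name)
    assert (meta.participant_id, meta.datatype, meta.date) == (pid, dtype, day)


def test_parse_ear_clip_carries_time():
    meta = parse_filename("SS0001-EAR_20190605192732.m4a")
    assert meta.datatype == "EAR"
    assert meta.date == date(2019, 6, 5)
    assert meta.clip_time == time(19, 27, 32)


@pytest.mark.parametrize(
    "bad, exc",
    [
        ("SS0001_GPS_20190605.txt", FilenameParseError),  # wrong delimiter
        ("SS0001-GPS.txt", FilenameParseError),  # day file without date
        ("SS0001-TEMPERATURE_20190605.txt", UnsupportedDatatypeError),
        ("SS0001-GPS_2019065.txt", FilenameParseError),  # 7-digit date
        ("SS0001-GPS_20191350.txt", FilenameParseError),  # month 13
        ("SS0001-AUDIO_20190605.csv", FilenameParseError),  # dated weekly file
        ("notes.docx", FilenameParseError),
        ("sub/SS0001-GPS_20190605.txt", FilenameParseError),  # not a bare name
    ],
)
def test_parse_filename_rejects_malformed(bad, exc):
    with pytest.raises(exc):
        parse_filename(bad)


_pid = st.from_regex(r"SS[A-Z0-9]{1,6}", fullmatch=True)
_date = st.dates(min_value=date(2015, 1, 1), max_value=date(2030, 12, 31))


@given(
    pid=_pid,
    dtype=st.sampled_from(["GPS", "PROXIMITY", "ACTIVITY"]),
    day=_date,
    ext=st.sampled_from(["txt", "csv"]),
)
def test_filename_roundtrip_day_files(pid, dtype, day, ext):
    meta = FileMeta(pid, dtype, day, None, ext)
    assert parse_filename(make_filename(meta)) == meta


@given(pid=_pid, day=_date, clip=st.times())
def test_filename_roundtrip_ear(pid, day, clip):
    clip = clip.replace(microsecond=0)
    meta = FileMeta(pid, "EAR", day, clip, "m4a")
    assert parse_filename(make_filename(meta)) == meta


# ---------------------------------------------------------------------------
# record file round trips
# ---------------------------------------------------------------------------

_ts = st.datetimes(
    min_value=datetime(2019, 6, 5), max_value=datetime(2019, 6, 5, 23, 59, 59)
).map(lambda t: t.replace(microsecond=0))


def _gps(pid):
    return st.builds(
        GpsFix,
        participant_id=st.just(pid),
        timestamp=_ts,
        lat=st.floats(-90, 90, allow_nan=False),
        lon=st.floats(-180, 180, allow_nan=False),
    )


def _prox(pid):
    def build(ts, detected, rssi):
        return ProximityReading(pid, ts, "BEACON01", detected, rssi if detected else None)

    return st.builds(
        build, _ts, st.booleans(), st.floats(-100, -30, allow_nan=False)
    )


def _act(pid):
    return st.builds(
        ActivityReading,
        participant_id=st.just(pid),
        timestamp=_ts,
        label=st.sampled_from(["still", "walking", "running", "in_vehicle", "cycling", "unknown"]),
    )


def _audio(pid):
    label = st.tuples(
        st.sampled_from(["Speech", "Music", "Vehicle", "Insect"]),
        st.floats(0, 1, allow_nan=False),
    )
    return st.builds(
        AudioClipPrediction,
        participant_id=st.just(pid),
        clip_start=_ts,
        duration=st.just(30.0),
        labels=st.lists(label, max_size=3).map(tuple),
    )


@pytest.mark.parametrize("records_strategy", [_gps, _prox, _act, _audio], ids=["gps", "proximity", "activity", "audio"])
@given(data=st.data())
def test_write_read_roundtrip(records_strategy, data, tmp_path_factory):
    records = data.draw(
        st.lists(records_strategy("SS0001"), min_size=1, max_size=10, unique_by=lambda r: r.timestamp)
    )
    folder = tmp_path_factory.mktemp("rt")
    meta = write_sensor_file(records, folder)
    back, report = read_sensor_file(folder / make_filename(meta), meta)
    assert sorted(records, key=lambda r: r.timestamp) == back
    assert report.rows_skipped == 0


def test_write_empty_then_read_empty(tmp_path):
    meta = write_sensor_file(
        [], tmp_path, datatype="GPS", participant_id="SS0001", file_date=date(2019, 6, 5)
    )
    assert make_filename(meta) == "SS0001-GPS_20190605.txt"
    back, _ = read_sensor_file(tmp_path / make_filename(meta), meta)
    assert back == []


def test_written_name_reparses_to_meta(tmp_path):
    records = [
        ActivityReading("SS0001", datetime(2019, 6, 5, 0, 15 * k % 60, 0).replace(hour=k // 4), "still")
        for k in range(96)
    ]
    meta = write_sensor_file(records, tmp_path)
    assert parse_filename(make_filename(meta)) == meta
    assert meta.date == date(2019, 6, 5)


def test_mixed_datatypes_rejected(tmp_path):
    recs = [
        GpsFix("SS0001", datetime(2019, 6, 5, 9), 27.7, 85.3),
        ActivityReading("SS0001", datetime(2019, 6, 5, 9), "still"),
    ]
    with pytest.raises(ValueError, match="mixed"):
        write_sensor_file(recs, tmp_path)


def test_out_of_bounds_row_skipped(tmp_path):
    path = tmp_path / "SS0001-GPS_20190605.txt"
    path.write_text(
        "timestamp,lat,lon\n"
        "2019-06-05T09:00:00,27.7,85.3\n"
        "2019-06-05T09:05:00,95.0,85.3\n"
        "2019-06-05T09:10:00,27.7,85.3\n"
    )
    records, report = read_sensor_file(path, parse_filename(path.name))
    assert len(records) == 2
    assert report.rows_skipped == 1


def test_mostly_malformed_file_is_corrupt(tmp_path):
    path = tmp_path / "SS0001-GPS_20190605.txt"
    path.write_text(
        "timestamp,lat,lon\n"
        "2019-06-05T09:00:00,27.7,85.3\n"
        "garbage,x,y\n"
        "more,garbage,here\n"
    )
    with pytest.raises(CorruptFileError):
        read_sensor_file(path, parse_filename(path.name))


def test_silent_audio_clip_roundtrip(tmp_path):
    clip = AudioClipPrediction("SS0001", datetime(2019, 6, 5, 9), 30.0, ())
    meta = write_sensor_file([clip], tmp_path)
    back, _ = read_sensor_file(tmp_path / make_filename(meta), meta)
    assert back == [clip]


# ---------------------------------------------------------------------------
# inbound ingest
# ---------------------------------------------------------------------------


def test_scan_inbound_loads_week(sim_week):
    folder, result = sim_week
    stores, report = scan_inbound(folder)
    store = stores["SS0001"]
    for dtype, n in [("GPS", 7), ("PROXIMITY", 7), ("ACTIVITY", 7), ("AUDIO", 1)]:
        assert report.file_counts[("SS0001", dtype)] == n
    assert len(store.provenance) == 22
    assert all(store.tables[t] for t in ("gps", "proximity", "activity", "audio"))


def test_scan_inbound_idempotent(sim_week):
    folder, _ = sim_week
    stores, _ = scan_inbound(folder)
    counts1 = {t: len(v) for t, v in stores["SS0001"].tables.items()}
    stores, report2 = scan_inbound(folder, stores)
    counts2 = {t: len(v) for t, v in stores["SS0001"].tables.items()}
    assert counts1 == counts2
    assert all(n == 0 for n in report2.records_added.values())


def test_scan_inbound_skips_foreign_files(tmp_path):
    (tmp_path / "notes.docx").write_text("meeting notes")
    (tmp_path / "SS0001-ACTIVITY_20190605.txt").write_text(
        "timestamp,label\n2019-06-05T09:00:00,walking\n"
    )
    stores, report = scan_inbound(tmp_path)
    assert report.files_unparsed == ["notes.docx"]
    assert len(stores["SS0001"].tables["activity"]) == 1


def test_scan_inbound_reject_policy(tmp_path):
    (tmp_path / "SS0009-ACTIVITY_20190605.txt").write_text(
        "timestamp,label\n2019-06-05T09:00:00,walking\n"
    )
    stores, report = scan_inbound(tmp_path, {}, on_unknown="reject")
    assert stores == {}
    assert report.files_rejected == ["SS0009-ACTIVITY_20190605.txt"]


def test_stored_dates_agree_with_file_meta(sim_week):
    folder, _ = sim_week
    stores, _ = scan_inbound(folder)
    store = stores["SS0001"]
    day_metas = [m for m in store.provenance if m.datatype in ("GPS", "PROXIMITY", "ACTIVITY")]
    meta_dates = {m.date for m in day_metas}
    for table in ("gps", "proximity", "activity"):
        assert {r.timestamp.date() for r in store.tables[table]} <= meta_dates
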