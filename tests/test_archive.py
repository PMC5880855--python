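import zipfile
from datetime import datetime, timedelta, timezone

import pytest

from helpers import count_data_lines, drop_member, read_table, rewrite_member
from homecage.archive import (
    SessionData,
    read_archive,
    render_member_tables,
    write_archive,
)
from homecage.errors import FormatError, IntegrityError
from homecage.model import Animal, TimeInterval, Visit
from homecage.synth import generate_experiment
from homecage.validation import check_integrity

from conftest import small_config

TZ = timezone(timedelta(hours=2))
T0 = datetime(2012, 8, 1, 13, 0, tzinfo=TZ)


def at(seconds):
    return T0 + timedelta(seconds=seconds)


def empty_session(**overrides):
    fields = dict(
        visits=(), animals={}, groups={}, environment=(), log=(), hardware=(),
        session_interval=TimeInterval(at(0), at(3600)),
        source_label="empty",
    )
    fields.update(overrides)
    return SessionData(**fields)


def test_round_trip_preserves_every_field(small_experiment, tmp_path):
    session = small_experiment[0][0]
    path = tmp_path / "session.zip"
    write_archive(session, path)
    assert read_archive(path) == session


def test_round_trip_of_empty_session(tmp_path):
    path = tmp_path / "empty.zip"
    write_archive(empty_session(), path)
    loaded = read_archive(path)
    assert loaded == empty_session()
    assert len(loaded.visits) == 0


def test_round_trip_preserves_non_ascii_names(tmp_path):
    animal = Animal(Name="Żaba-Müsli", Sex="female", Tag="981x")
    session = empty_session(
        animals={"Żaba-Müsli": animal},
        visits=(
            Visit(Start=at(1), End=at(2), Cage=1, Corner=1, Animal=animal),
        ),
    )
    path = tmp_path / "utf8.zip"
    write_archive(session, path)
    loaded = read_archive(path)
    assert loaded.visits[0].Animal.Name == "Żaba-Müsli"
    assert loaded == session


def test_loaded_counts_equal_table_line_counts(small_archive):
    session = read_archive(small_archive)
    assert len(session.visits) == count_data_lines(small_archive, "Visits.txt")
    n_pokes = sum(len(v.Nosepokes) for v in session.visits)
    assert n_pokes == count_data_lines(small_archive, "Nosepokes.txt")
    assert len(session.log) == count_data_lines(small_archive, "Log.txt")
    assert len(session.environment) == count_data_lines(
        small_archive, "Environment.txt"
    )
    assert len(session.hardware) == count_data_lines(
        small_archive, "HardwareEvents.txt"
    )


def test_rewriting_a_loaded_archive_is_byte_stable(small_archive, tmp_path):
    session = read_archive(small_archive)
    tables = render_member_tables(session)
    with zipfile.ZipFile(small_archive) as original:
        for member, text in tables.items():
            assert original.read(member).decode("utf-8") == text


def test_missing_member_is_a_format_error_naming_it(small_archive, tmp_path):
    broken = tmp_path / "broken.zip"
    drop_member(small_archive, broken, "Nosepokes.txt")
    with pytest.raises(FormatError, match="Nosepokes.txt"):
        read_archive(broken)


def test_dangling_visit_id_is_an_integrity_error_citing_rows(
    small_archive, tmp_path
):
    broken = tmp_path / "dangling.zip"

    def edit(text):
        lines = text.split("\n")
        cells = lines[1].split("\t")
        cells[0] = "99999"
        lines[1] = "\t".join(cells)
        return "\n".join(lines)

    rewrite_member(small_archive, broken, "Nosepokes.txt", edit)
    with pytest.raises(IntegrityError, match="99999"):
        read_archive(broken)


def test_unknown_animal_reference_is_an_integrity_error(small_archive, tmp_path):
    broken = tmp_path / "ghost.zip"

    def edit(text):
        lines = text.split("\n")
        cells = lines[1].split("\t")
        cells[1] = "Casper"
        lines[1] = "\t".join(cells)
        return "\n".join(lines)

    rewrite_member(small_archive, broken, "Visits.txt", edit)
    with pytest.raises(IntegrityError, match="Casper"):
        read_archive(broken)


def test_naive_timestamp_is_a_format_error(small_archive, tmp_path):
    broken = tmp_path / "naive.zip"

    def edit(text):
        lines = text.split("\n")
        cells = lines[1].split("\t")
        cells[4] = cells[4].rsplit(" ", 1)[0]  # strip the UTC offset
        lines[1] = "\t".join(cells)
        return "\n".join(lines)

    rewrite_member(small_archive, broken, "Visits.txt", edit)
    with pytest.raises(FormatError, match="naive"):
        read_archive(broken)


def test_out_of_bounds_nosepoke_survives_loading_unchanged(
    small_archive, tmp_path
):
    """A nosepoke edited to start before its visit is loaded as-is (no
    implicit filtering); validation flags it afterwards."""
    tampered = tmp_path / "tampered.zip"
    moved_start = {}

    def edit(text):
        lines = text.split("\n")
        cells = lines[1].split("\t")
        early = (
            datetime.strptime(cells[2], "%Y-%m-%d %H:%M:%S.%f %z")
            - timedelta(hours=5)
        )
        cells[2] = (
            early.strftime("%Y-%m-%d %H:%M:%S")
            + f".{early.microsecond // 1000:03d} "
            + early.strftime("%z")
        )
        moved_start["value"] = early
        lines[1] = "\t".join(cells)
        return "\n".join(lines)

    rewrite_member(small_archive, tampered, "Nosepokes.txt", edit)
    pristine = read_archive(small_archive)
    loaded = read_archive(tampered)

    n_pokes = sum(len(v.Nosepokes) for v in loaded.visits)
    assert n_pokes == sum(len(v.Nosepokes) for v in pristine.visits)
    all_pokes = [p for v in loaded.visits for p in v.Nosepokes]
    assert any(p.Start == moved_start["value"] for p in all_pokes)
    kinds = [f.kind for f in check_integrity(loaded)]
    assert "nosepoke_outside_visit" in kinds


def test_sub_millisecond_timestamps_are_rejected_on_write(tmp_path):
    session = empty_session(
        session_interval=TimeInterval(at(0), at(0) + timedelta(microseconds=1)),
    )
    with pytest.raises(FormatError, match="millisecond"):
        write_archive(session, tmp_path / "precision.zip")


def test_archive_is_deterministic_bytes(tmp_path):
    sessions, _, _ = generate_experiment(small_config(seed=5))
    first, second = tmp_path / "a.zip", tmp_path / "b.zip"
    write_archive(sessions[0], first)
    write_archive(sessions[0], second)
    assert first.read_bytes() == second.read_bytes()


def test_visit_nosepoke_links_resolved_via_visit_id(small_archive):
    session = read_archive(small_archive)
    table = read_table(small_archive, "Nosepokes.txt")
    by_vid = {}
    for row in table:
        by_vid.setdefault(row["VisitID"], []).append(row)
    visit_rows = read_table(small_archive, "Visits.txt")
    # visits are written time-sorted, so row order matches session.visits
    for row, visit in zip(visit_rows, session.visits):
        assert len(visit.Nosepokes) == len(by_vid.get(row["VisitID"], []))
        assert all(p.Visit is visit for p in visit.Nosepokes)
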