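"""Session archives: a documented ZIP dialect (``MCD-1``) and session merging.

A recording session is stored as a ZIP archive of tab-delimited UTF-8 text
tables, one per record kind, mirroring the records the cage controller
writes.  The exact member files, column orders and value encodings are
documented in ``FORMAT.md`` at the repository root.  The dialect is
self-consistent and round-trips exactly: ``read_archive(write_archive(s))``
reproduces ``s`` field by field, and re-writing a loaded archive reproduces
the member tables byte for byte.

The loader performs **no implicit filtering**: every parsable row in the
tables becomes a record, including rows that are mutually inconsistent
(e.g. a nosepoke outside its visit's bounds).  Consistency problems are the
business of :mod:`homecage.validation`, never of the loader.
"""

from __future__ import annotations

import io
import zipfile
from dataclasses import dataclass
from datetime import datetime
from types import MappingProxyType
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

from .errors import FormatError, IntegrityError, MergeConflictError
from .model import (
    Animal,
    EnvironmentalConditions,
    Group,
    HardwareEvent,
    LogEntry,
    Nosepoke,
    TimeInterval,
    Visit,
)

__all__ = [
    "DIALECT_VERSION",
    "SessionData",
    "DataSet",
    "read_archive",
    "write_archive",
    "merge_sessions",
]

DIALECT_VERSION = "MCD-1"

_MEMBERS = (
    "Session.txt",
    "Animals.txt",
    "Groups.txt",
    "Visits.txt",
    "Nosepokes.txt",
    "Environment.txt",
    "Log.txt",
    "HardwareEvents.txt",
)

_TIME_FORMAT = "%Y-%m-%d %H:%M:%S.%f %z"

# Fixed member metadata so identical sessions produce identical archives.
_ZIP_DATE = (1980, 1, 1, 0, 0, 0)


# --------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class SessionData:
    """One loaded recording session, fully materialized in memory.

    All record sequences are stored time-sorted (stably, preserving source
    row order for ties).  ``animals`` and ``groups`` map names to records;
    every ``Visit.Animal`` is an object from ``animals``.
    """

    visits: tuple
    animals: Mapping[str, Animal]
    groups: Mapping[str, Group]
    environment: tuple
    log: tuple
    hardware: tuple
    session_interval: TimeInterval
    source_label: str = "session"

    def __post_init__(self) -> None:
        object.__setattr__(self, "visits", tuple(self.visits))
        object.__setattr__(self, "environment", tuple(self.environment))
        object.__setattr__(self, "log", tuple(self.log))
        object.__setattr__(self, "hardware", tuple(self.hardware))
        object.__setattr__(self, "animals", MappingProxyType(dict(self.animals)))
        object.__setattr__(self, "groups", MappingProxyType(dict(self.groups)))
        for visit in self.visits:
            if visit.Animal.Name not in self.animals:
                raise IntegrityError(
                    f"visit at {visit.Start} references unknown animal "
                    f"{visit.Animal.Name!r}"
                )


@dataclass(frozen=True)
class DataSet(SessionData):
    """One or more merged sessions presented as a single queryable object."""

    sources: tuple = ()

    def __post_init__(self) -> None:
        super().__post_init__()
        object.__setattr__(self, "sources", tuple(self.sources))


# --------------------------------------------------------------------------
# value encoding


def format_timestamp(moment: datetime) -> str:
    """Render an aware timestamp as ``YYYY-MM-DD HH:MM:SS.mmm ±HHMM``."""
    if moment.tzinfo is None or moment.tzinfo.utcoffset(moment) is None:
        raise FormatError(f"cannot serialize naive timestamp {moment!r}")
    if moment.microsecond % 1000:
        raise FormatError(
            f"timestamp {moment!r} has sub-millisecond precision; the "
            f"{DIALECT_VERSION} dialect stores milliseconds"
        )
    base = moment.strftime("%Y-%m-%d %H:%M:%S")
    offset = moment.strftime("%z")
    return f"{base}.{moment.microsecond // 1000:03d} {offset}"


def parse_timestamp(text: str, where: str = "") -> datetime:
    """Parse a dialect timestamp; naive values are a format error."""
    try:
        return datetime.strptime(text, _TIME_FORMAT)
    except ValueError:
        pass
    try:
        datetime.strptime(text, "%Y-%m-%d %H:%M:%S.%f")
    except ValueError:
        raise FormatError(f"unparseable timestamp {text!r}{where}") from None
    raise FormatError(f"naive timestamp {text!r} (missing UTC offset){where}")


def _check_field(value: str, what: str) -> str:
    if "\t" in value or "\n" in value or "\r" in value:
        raise FormatError(f"{what} may not contain tabs or newlines: {value!r}")
    return value


def _opt_int(text: str, what: str) -> Optional[int]:
    if text == "":
        return None
    try:
        return int(text)
    except ValueError:
        raise FormatError(f"{what}: expected integer, got {text!r}") from None


def _int(text: str, what: str) -> int:
    value = _opt_int(text, what)
    if value is None:
        raise FormatError(f"{what}: missing mandatory integer")
    return value


def _float(text: str, what: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise FormatError(f"{what}: expected number, got {text!r}") from None


class _Table:
    """A tab-delimited member table with a mandatory header line."""

    def __init__(self, name: str, text: str, expected_header: Sequence[str]):
        self.name = name
        lines = text.split("\n")
        if lines and lines[-1] == "":
            lines.pop()
        if not lines:
            raise FormatError(f"{name}: empty member, header line required")
        header = lines[0].split("\t")
        if header != list(expected_header):
            raise FormatError(
                f"{name}: bad header {header!r}, expected {list(expected_header)!r}"
            )
        self.rows: List[Tuple[int, List[str]]] = []
        for lineno, line in enumerate(lines[1:], start=2):
            cells = line.split("\t")
            if len(cells) != len(header):
                raise FormatError(
                    f"{name} line {lineno}: {len(cells)} fields, "
                    f"expected {len(header)}"
                )
            self.rows.append((lineno, cells))


_HEADERS = {
    "Animals.txt": ("Name", "Sex", "Tag"),
    "Groups.txt": ("Name", "Animals"),
    "Visits.txt": (
        "VisitID", "Animal", "Cage", "Corner", "Start", "End", "CornerCondition",
    ),
    "Nosepokes.txt": (
        "VisitID", "Side", "Start", "End", "SideCondition",
        "LickNumber", "LickDuration",
    ),
    "Environment.txt": ("DateTime", "Cage", "Illumination", "Temperature"),
    "Log.txt": ("DateTime", "Category", "Type", "Cage", "Corner", "Side", "Notes"),
    "HardwareEvents.txt": ("DateTime", "Cage", "Corner", "Side", "Type", "State"),
}


# --------------------------------------------------------------------------
# reading


def read_archive(path) -> SessionData:
    """Load one session archive; every parsable record is returned as-is."""
    try:
        archive = zipfile.ZipFile(path, "r")
    except (FileNotFoundError, zipfile.BadZipFile) as exc:
        raise FormatError(f"cannot open archive {path}: {exc}") from exc
    with archive:
        present = set(archive.namelist())
        for member in _MEMBERS:
            if member not in present:
                raise FormatError(f"archive {path} is missing member {member}")
        texts = {m: archive.read(m).decode("utf-8") for m in _MEMBERS}

    session_info = _parse_session_member(texts["Session.txt"])
    animals = _parse_animals(texts["Animals.txt"])
    groups = _parse_groups(texts["Groups.txt"], animals)
    pokes_by_visit = _parse_nosepokes(texts["Nosepokes.txt"])
    visits, seen_ids = _parse_visits(texts["Visits.txt"], animals, pokes_by_visit)
    dangling = sorted(set(pokes_by_visit) - seen_ids)
    if dangling:
        rows = [
            str(lineno)
            for vid in dangling
            for lineno, _ in pokes_by_visit[vid]
        ]
        raise IntegrityError(
            f"Nosepokes.txt references unknown VisitID(s) {dangling} "
            f"(rows {', '.join(rows)})"
        )
    environment = _parse_environment(texts["Environment.txt"])
    log = _parse_log(texts["Log.txt"])
    hardware = _parse_hardware(texts["HardwareEvents.txt"])

    return SessionData(
        visits=_stable_time_sort(visits, "Start"),
        animals=animals,
        groups=groups,
        environment=_stable_time_sort(environment, "DateTime"),
        log=_stable_time_sort(log, "DateTime"),
        hardware=_stable_time_sort(hardware, "DateTime"),
        session_interval=session_info[0],
        source_label=session_info[1],
    )


def _stable_time_sort(records: Iterable, attribute: str) -> tuple:
    return tuple(sorted(records, key=lambda r: getattr(r, attribute)))


def _parse_session_member(text: str) -> Tuple[TimeInterval, str]:
    values = {}
    for lineno, line in enumerate(text.split("\n"), start=1):
        if not line:
            continue
        key, sep, value = line.partition("\t")
        if not sep:
            raise FormatError(f"Session.txt line {lineno}: expected key<TAB>value")
        values[key] = value
    for key in ("Version", "Label", "Start", "End"):
        if key not in values:
            raise FormatError(f"Session.txt: missing property {key!r}")
    if values["Version"] != DIALECT_VERSION:
        raise FormatError(
            f"Session.txt: unsupported dialect version {values['Version']!r}, "
            f"expected {DIALECT_VERSION!r}"
        )
    interval = TimeInterval(
        parse_timestamp(values["Start"], " in Session.txt"),
        parse_timestamp(values["End"], " in Session.txt"),
    )
    return interval, values["Label"]


def _parse_animals(text: str) -> Mapping[str, Animal]:
    table = _Table("Animals.txt", text, _HEADERS["Animals.txt"])
    animals: dict = {}
    for lineno, (name, sex, tags) in table.rows:
        if name in animals:
            raise IntegrityError(f"Animals.txt line {lineno}: duplicate name {name!r}")
        animals[name] = Animal(
            Name=name, Sex=sex, Tag=frozenset(tags.split(";")),
        )
    return animals


def _parse_groups(text: str, animals: Mapping[str, Animal]) -> Mapping[str, Group]:
    table = _Table("Groups.txt", text, _HEADERS["Groups.txt"])
    groups: dict = {}
    for lineno, (name, members) in table.rows:
        if name in groups:
            raise IntegrityError(f"Groups.txt line {lineno}: duplicate group {name!r}")
        resolved = []
        for member in members.split(";") if members else []:
            if member not in animals:
                raise IntegrityError(
                    f"Groups.txt line {lineno}: unknown animal {member!r}"
                )
            resolved.append(animals[member])
        groups[name] = Group(Name=name, Animals=tuple(resolved))
    return groups


def _parse_nosepokes(text: str):
    table = _Table("Nosepokes.txt", text, _HEADERS["Nosepokes.txt"])
    by_visit: dict = {}
    for lineno, cells in table.rows:
        vid = _int(cells[0], f"Nosepokes.txt line {lineno} VisitID")
        poke = Nosepoke(
            Start=parse_timestamp(cells[2], f" (Nosepokes.txt line {lineno})"),
            End=parse_timestamp(cells[3], f" (Nosepokes.txt line {lineno})"),
            Side=_int(cells[1], f"Nosepokes.txt line {lineno} Side"),
            SideCondition=_int(cells[4], f"Nosepokes.txt line {lineno} SideCondition"),
            LickNumber=_int(cells[5], f"Nosepokes.txt line {lineno} LickNumber"),
            LickDuration=_float(cells[6], f"Nosepokes.txt line {lineno} LickDuration"),
        )
        by_visit.setdefault(vid, []).append((lineno, poke))
    return by_visit


def _parse_visits(text: str, animals, pokes_by_visit):
    table = _Table("Visits.txt", text, _HEADERS["Visits.txt"])
    visits = []
    seen_ids = set()
    for lineno, cells in table.rows:
        vid = _int(cells[0], f"Visits.txt line {lineno} VisitID")
        if vid in seen_ids:
            raise IntegrityError(f"Visits.txt line {lineno}: duplicate VisitID {vid}")
        seen_ids.add(vid)
        name = cells[1]
        if name not in animals:
            raise IntegrityError(
                f"Visits.txt line {lineno}: unknown animal {name!r}"
            )
        pokes = tuple(p for _, p in pokes_by_visit.get(vid, []))
        visits.append(
            Visit(
                Start=parse_timestamp(cells[4], f" (Visits.txt line {lineno})"),
                End=parse_timestamp(cells[5], f" (Visits.txt line {lineno})"),
                Cage=_int(cells[2], f"Visits.txt line {lineno} Cage"),
                Corner=_int(cells[3], f"Visits.txt line {lineno} Corner"),
                Animal=animals[name],
                CornerCondition=_int(
                    cells[6], f"Visits.txt line {lineno} CornerCondition"
                ),
                Nosepokes=pokes,
            )
        )
    return visits, seen_ids


def _parse_environment(text: str) -> list:
    table = _Table("Environment.txt", text, _HEADERS["Environment.txt"])
    return [
        EnvironmentalConditions(
            DateTime=parse_timestamp(c[0], f" (Environment.txt line {lineno})"),
            Cage=_int(c[1], f"Environment.txt line {lineno} Cage"),
            Illumination=_int(c[2], f"Environment.txt line {lineno} Illumination"),
            Temperature=_float(c[3], f"Environment.txt line {lineno} Temperature"),
        )
        for lineno, c in table.rows
    ]


def _parse_log(text: str) -> list:
    table = _Table("Log.txt", text, _HEADERS["Log.txt"])
    return [
        LogEntry(
            DateTime=parse_timestamp(c[0], f" (Log.txt line {lineno})"),
            Category=c[1],
            Type=c[2],
            Cage=_opt_int(c[3], f"Log.txt line {lineno} Cage"),
            Corner=_opt_int(c[4], f"Log.txt line {lineno} Corner"),
            Side=_opt_int(c[5], f"Log.txt line {lineno} Side"),
            Notes=c[6],
        )
        for lineno, c in table.rows
    ]


def _parse_hardware(text: str) -> list:
    table = _Table("HardwareEvents.txt", text, _HEADERS["HardwareEvents.txt"])
    return [
        HardwareEvent(
            DateTime=parse_timestamp(c[0], f" (HardwareEvents.txt line {lineno})"),
            Cage=_int(c[1], f"HardwareEvents.txt line {lineno} Cage"),
            Corner=_int(c[2], f"HardwareEvents.txt line {lineno} Corner"),
            Side=_opt_int(c[3], f"HardwareEvents.txt line {lineno} Side"),
            Type=c[4],
            State=_int(c[5], f"HardwareEvents.txt line {lineno} State"),
        )
        for lineno, c in table.rows
    ]


# --------------------------------------------------------------------------
# writing


def _opt(value) -> str:
    return "" if value is None else str(value)


def render_member_tables(session: SessionData) -> Mapping[str, str]:
    """Render a session to its member-table texts (canonical form)."""
    tables = {}

    lines = ["\t".join(_HEADERS["Animals.txt"])]
    for animal in session.animals.values():
        _check_field(animal.Name, "Animal.Name")
        lines.append(
            "\t".join((animal.Name, animal.Sex, ";".join(sorted(animal.Tag))))
        )
    tables["Animals.txt"] = "\n".join(lines) + "\n"

    lines = ["\t".join(_HEADERS["Groups.txt"])]
    for group in session.groups.values():
        _check_field(group.Name, "Group.Name")
        lines.append(
            "\t".join((group.Name, ";".join(a.Name for a in group.Animals)))
        )
    tables["Groups.txt"] = "\n".join(lines) + "\n"

    visit_lines = ["\t".join(_HEADERS["Visits.txt"])]
    poke_lines = ["\t".join(_HEADERS["Nosepokes.txt"])]
    for vid, visit in enumerate(session.visits, start=1):
        visit_lines.append(
            "\t".join(
                (
                    str(vid),
                    visit.Animal.Name,
                    str(visit.Cage),
                    str(visit.Corner),
                    format_timestamp(visit.Start),
                    format_timestamp(visit.End),
                    str(visit.CornerCondition),
                )
            )
        )
        for poke in visit.Nosepokes:
            poke_lines.append(
                "\t".join(
                    (
                        str(vid),
                        str(poke.Side),
                        format_timestamp(poke.Start),
                        format_timestamp(poke.End),
                        str(poke.SideCondition),
                        str(poke.LickNumber),
                        str(poke.LickDuration),
                    )
                )
            )
    tables["Visits.txt"] = "\n".join(visit_lines) + "\n"
    tables["Nosepokes.txt"] = "\n".join(poke_lines) + "\n"

    lines = ["\t".join(_HEADERS["Environment.txt"])]
    for sample in session.environment:
        lines.append(
            "\t".join(
                (
                    format_timestamp(sample.DateTime),
                    str(sample.Cage),
                    str(sample.Illumination),
                    str(sample.Temperature),
                )
            )
        )
    tables["Environment.txt"] = "\n".join(lines) + "\n"

    lines = ["\t".join(_HEADERS["Log.txt"])]
    for entry in session.log:
        _check_field(entry.Notes, "LogEntry.Notes")
        lines.append(
            "\t".join(
                (
                    format_timestamp(entry.DateTime),
                    entry.Category,
                    entry.Type,
                    _opt(entry.Cage),
                    _opt(entry.Corner),
                    _opt(entry.Side),
                    entry.Notes,
                )
            )
        )
    tables["Log.txt"] = "\n".join(lines) + "\n"

    lines = ["\t".join(_HEADERS["HardwareEvents.txt"])]
    for event in session.hardware:
        lines.append(
            "\t".join(
                (
                    format_timestamp(event.DateTime),
                    str(event.Cage),
                    str(event.Corner),
                    _opt(event.Side),
                    event.Type,
                    str(event.State),
                )
            )
        )
    tables["HardwareEvents.txt"] = "\n".join(lines) + "\n"

    tables["Session.txt"] = (
        f"Version\t{DIALECT_VERSION}\n"
        f"Label\t{_check_field(session.source_label, 'source_label')}\n"
        f"Start\t{format_timestamp(session.session_interval.start)}\n"
        f"End\t{format_timestamp(session.session_interval.end)}\n"
    )
    return tables


def write_archive(session: SessionData, path) -> None:
    """Write one session as a ``MCD-1`` ZIP archive (deterministic bytes)."""
    tables = render_member_tables(session)
    buffer = io.BytesIO()
    with zipfile.ZipFile(buffer, "w", compression=zipfile.ZIP_DEFLATED) as archive:
        for member in _MEMBERS:
            info = zipfile.ZipInfo(member, date_time=_ZIP_DATE)
            info.compress_type = zipfile.ZIP_DEFLATED
            info.external_attr = 0o644 << 16
            archive.writestr(info, tables[member])
    with open(path, "wb") as handle:
        handle.write(buffer.getvalue())


# --------------------------------------------------------------------------
# merging


def _merge_sex(a: str, b: str, name: str) -> str:
    if a == b:
        return a
    if a == "unknown":
        return b
    if b == "unknown":
        return a
    raise MergeConflictError(
        f"animal {name!r} recorded with conflicting sexes {a!r} and {b!r}"
    )


def merge_sessions(sessions: Sequence[SessionData]) -> DataSet:
    """Merge recording sessions into one dataset.

    Record sequences are concatenated in input order and re-sorted stably by
    their time field, so equal timestamps keep (source order, row order).
    Nothing is deduplicated: every record of every input survives, and
    per-kind counts of the result equal the sums over inputs.

    Animals are unified across sessions: the same transponder tag must always
    belong to one animal name, and one name accumulates the union of its tags
    across sessions (a mouse may be re-tagged between sessions).  Conflicts
    (one tag under two names, or one name with incompatible sexes) abort the
    merge.
    """
    sessions = list(sessions)
    if not sessions:
        raise MergeConflictError("merge_sessions needs at least one session")

    merged_names: dict = {}  # name -> (sex, set of tags)
    tag_owner: dict = {}  # tag -> name
    for session in sessions:
        for animal in session.animals.values():
            if animal.Name in merged_names:
                sex, tags = merged_names[animal.Name]
                sex = _merge_sex(sex, animal.Sex, animal.Name)
                merged_names[animal.Name] = (sex, tags | animal.Tag)
            else:
                merged_names[animal.Name] = (animal.Sex, set(animal.Tag))
            for tag in animal.Tag:
                owner = tag_owner.setdefault(tag, animal.Name)
                if owner != animal.Name:
                    raise MergeConflictError(
                        f"tag {tag!r} belongs to both {owner!r} and "
                        f"{animal.Name!r}"
                    )
    animals = {
        name: Animal(Name=name, Sex=sex, Tag=frozenset(tags))
        for name, (sex, tags) in merged_names.items()
    }

    groups: dict = {}  # name -> ordered member names
    for session in sessions:
        for group in session.groups.values():
            members = groups.setdefault(group.Name, [])
            for member in group.Animals:
                if member.Name not in members:
                    members.append(member.Name)
    merged_groups = {
        name: Group(Name=name, Animals=tuple(animals[m] for m in members))
        for name, members in groups.items()
    }

    visits = []
    for session in sessions:
        for visit in session.visits:
            merged = animals[visit.Animal.Name]
            if merged == visit.Animal:
                visits.append(visit)
            else:  # re-bind to the unified animal record
                visits.append(
                    Visit(
                        Start=visit.Start,
                        End=visit.End,
                        Cage=visit.Cage,
                        Corner=visit.Corner,
                        Animal=merged,
                        CornerCondition=visit.CornerCondition,
                        Nosepokes=visit.Nosepokes,
                    )
                )

    environment = [s for session in sessions for s in session.environment]
    log = [e for session in sessions for e in session.log]
    hardware = [e for session in sessions for e in session.hardware]

    sources: list = []
    for session in sessions:
        sources.extend(getattr(session, "sources", (session.source_label,)))

    interval = TimeInterval(
        min(s.session_interval.start for s in sessions),
        max(s.session_interval.end for s in sessions),
    )
    return DataSet(
        visits=_stable_time_sort(visits, "Start"),
        animals=animals,
        groups=merged_groups,
        environment=_stable_time_sort(environment, "DateTime"),
        log=_stable_time_sort(log, "DateTime"),
        hardware=_stable_time_sort(hardware, "DateTime"),
        session_interval=interval,
        source_label="+".join(sources),
        sources=tuple(sources),
    )
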