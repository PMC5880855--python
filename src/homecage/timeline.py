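"""Experiment timelines: named, timezone-anchored phases of an experiment.

The timeline file is an INI derivative: one section per phase, holding the
phase's local wall-clock boundaries and the IANA timezone those boundaries
are expressed in::

    [PP dark]
    start = 2012-08-01 13:00
    end = 2012-08-02 01:00
    tzinfo = Etc/GMT-2

A ``[DEFAULT]`` section may provide a ``tzinfo`` inherited by sections that
lack one.  Full-line ``#`` comments are allowed.  Phase names are
case-sensitive, may contain spaces, and may overlap in time (a phase and its
dark half commonly do).

Wall-clock boundaries are resolved onto the absolute (UTC) axis using the
zone's rules, including daylight-saving transitions: a wall-clock time that
occurs twice resolves to its earlier occurrence, and one skipped by a DST
gap is shifted forward past the gap; both cases emit a warning.
"""

from __future__ import annotations

import configparser
import warnings
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Iterator, Tuple
from zoneinfo import ZoneInfo, ZoneInfoNotFoundError

from .errors import FormatError, RecordLookupError
from .model import TimeInterval

__all__ = ["Phase", "Timeline", "parse_timeline", "write_timeline",
           "phase_bounds", "localize"]

_WALL_FORMATS = ("%Y-%m-%d %H:%M", "%Y-%m-%d %H:%M:%S")


def _parse_wall_clock(text: str, where: str) -> datetime:
    for fmt in _WALL_FORMATS:
        try:
            return datetime.strptime(text, fmt)
        except ValueError:
            continue
    raise FormatError(
        f"{where}: cannot parse local time {text!r} "
        f"(expected YYYY-MM-DD HH:MM[:SS])"
    )


def localize(naive: datetime, zone: ZoneInfo, where: str = "") -> datetime:
    """Attach a zone to a naive wall-clock time, resolving DST edge cases.

    Ambiguous times (the clock shows them twice when DST ends) resolve to
    the earlier occurrence; nonexistent times (skipped when DST starts) are
    shifted forward by the length of the gap.  Both resolutions warn.
    """
    earlier = naive.replace(tzinfo=zone, fold=0)
    later = naive.replace(tzinfo=zone, fold=1)
    if earlier.utcoffset() != later.utcoffset():
        warnings.warn(
            f"ambiguous local time {naive} in zone {zone.key}{where}; "
            f"using the earlier occurrence",
            stacklevel=2,
        )
        return earlier
    # A nonexistent local time maps to an instant whose wall clock differs
    # from what was written; normalizing through UTC shifts it past the gap.
    normalized = earlier.astimezone(timezone.utc).astimezone(zone)
    if normalized.replace(tzinfo=None) != naive:
        warnings.warn(
            f"nonexistent local time {naive} in zone {zone.key}{where}; "
            f"shifted forward to {normalized.replace(tzinfo=None)}",
            stacklevel=2,
        )
        return normalized
    return earlier


@dataclass(frozen=True)
class Phase:
    """A named absolute time interval of the experiment."""

    name: str
    interval: TimeInterval

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("phase name must be non-empty")
        if self.interval.start >= self.interval.end:
            raise FormatError(
                f"phase {self.name!r}: start must precede end"
            )

    @property
    def start(self) -> datetime:
        return self.interval.start

    @property
    def end(self) -> datetime:
        return self.interval.end

    @property
    def tzinfo(self):
        """Zone the phase boundaries were declared in."""
        return self.interval.start.tzinfo


class Timeline:
    """Ordered collection of named phases with case-sensitive lookup."""

    def __init__(self, phases):
        self._phases = {}
        for phase in phases:
            if phase.name in self._phases:
                raise FormatError(f"duplicate phase name {phase.name!r}")
            self._phases[phase.name] = phase

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(self._phases)

    def __len__(self) -> int:
        return len(self._phases)

    def __iter__(self) -> Iterator[Phase]:
        return iter(self._phases.values())

    def __contains__(self, name: str) -> bool:
        return name in self._phases

    def __getitem__(self, name: str) -> Phase:
        try:
            return self._phases[name]
        except KeyError:
            raise RecordLookupError(
                f"unknown phase {name!r}; available phases: "
                f"{', '.join(repr(n) for n in self._phases)}"
            ) from None

    def bounds(self, name: str) -> TimeInterval:
        """Absolute half-open interval of the named phase."""
        return self[name].interval

    def __eq__(self, other) -> bool:
        if not isinstance(other, Timeline):
            return NotImplemented
        return self._phases == other._phases


def phase_bounds(timeline: Timeline, name: str) -> TimeInterval:
    """Functional alias for :meth:`Timeline.bounds`."""
    return timeline.bounds(name)


def parse_timeline(path) -> Timeline:
    """Parse a timeline file into a :class:`Timeline`."""
    parser = configparser.ConfigParser(
        comment_prefixes=("#",),
        inline_comment_prefixes=None,
        interpolation=None,
        strict=True,
    )
    try:
        with open(path, "r", encoding="utf-8") as handle:
            parser.read_file(handle, source=str(path))
    except FileNotFoundError:
        raise FormatError(f"timeline file {path} does not exist") from None
    except configparser.DuplicateSectionError as exc:
        raise FormatError(f"timeline {path}: duplicate section {exc.section!r}") from exc
    except configparser.Error as exc:
        raise FormatError(f"timeline {path}: {exc}") from exc

    phases = []
    for section in parser.sections():
        values = parser[section]
        for prop in ("start", "end", "tzinfo"):
            if prop not in values or not values[prop].strip():
                raise FormatError(
                    f"timeline {path}: section [{section}] is missing "
                    f"property {prop!r}"
                )
        try:
            zone = ZoneInfo(values["tzinfo"].strip())
        except (ZoneInfoNotFoundError, ValueError, KeyError):
            raise FormatError(
                f"timeline {path}: section [{section}] names unknown "
                f"timezone {values['tzinfo'].strip()!r}"
            ) from None
        where = f" (section [{section}] of {path})"
        start = localize(
            _parse_wall_clock(values["start"].strip(), f"section [{section}] start"),
            zone, where,
        )
        end = localize(
            _parse_wall_clock(values["end"].strip(), f"section [{section}] end"),
            zone, where,
        )
        if end <= start:
            raise FormatError(
                f"timeline {path}: section [{section}] has end <= start"
            )
        phases.append(Phase(name=section, interval=TimeInterval(start, end)))
    return Timeline(phases)


def write_timeline(timeline: Timeline, path) -> None:
    """Serialize a timeline back to the INI dialect (reparses to equal intervals)."""
    lines = []
    for phase in timeline:
        zone = phase.tzinfo
        key = getattr(zone, "key", None)
        if key is None:
            raise FormatError(
                f"phase {phase.name!r} is not anchored to a named IANA zone; "
                f"cannot serialize"
            )
        lines.append(f"[{phase.name}]")
        lines.append(f"start = {phase.start.strftime('%Y-%m-%d %H:%M:%S')}")
        lines.append(f"end = {phase.end.strftime('%Y-%m-%d %H:%M:%S')}")
        lines.append(f"tzinfo = {key}")
        lines.append("")
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\n".join(lines))
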