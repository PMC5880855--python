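"""Immutable domain records for operant-corner cage monitoring data.

The record types mirror what the cage control software writes: a ``Visit`` is
one entry of one RFID-tagged mouse into one conditioning corner, bounded in
time; a ``Nosepoke`` is one snout insertion into one of the two side openings
of that corner during the visit.  Environmental samples, log entries and
hardware events are side channels recorded by the same controller.

All records are frozen dataclasses: once constructed they cannot be modified,
which lets analyses share them freely.  Every timestamp in the system is
timezone-aware; naive datetimes are rejected at construction, and all
comparisons happen on the absolute (UTC) axis, which ``datetime`` guarantees
for aware values.

Side numbering convention
-------------------------
Sides are numbered 1-8 over the whole cage, two per corner: sides ``2k-1``
(odd, *left*) and ``2k`` (even, *right*) belong to corner ``k``.  The
``Door`` property of a nosepoke translates the integer side into the
``"left"`` / ``"right"`` label used in analyses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterator, Optional, Sequence

from .errors import DomainError, FormatError

__all__ = [
    "SEXES",
    "LEFT",
    "RIGHT",
    "door_from_side",
    "corner_of_side",
    "seconds_between",
    "TimeInterval",
    "Animal",
    "Group",
    "Nosepoke",
    "Visit",
    "EnvironmentalConditions",
    "LogEntry",
    "HardwareEvent",
]

SEXES = ("female", "male", "unknown")

LEFT = "left"
RIGHT = "right"


def _require_aware(value: datetime, what: str) -> None:
    if not isinstance(value, datetime):
        raise FormatError(f"{what} must be a datetime, got {type(value).__name__}")
    if value.tzinfo is None or value.tzinfo.utcoffset(value) is None:
        raise FormatError(f"{what} must be timezone-aware, got naive {value!r}")


def _require_int(value, what: str) -> int:
    if isinstance(value, bool) or not isinstance(value, int):
        raise DomainError(f"{what} must be an integer, got {value!r}")
    return value


def door_from_side(side: int) -> str:
    """Translate an integer side number (1-8) to its door label.

    Odd sides are the left door of their corner, even sides the right door.
    """
    _require_int(side, "side")
    if not 1 <= side <= 8:
        raise DomainError(f"side must be in 1..8, got {side}")
    return LEFT if side % 2 else RIGHT


def corner_of_side(side: int) -> int:
    """Return the corner (1-4) that an integer side number (1-8) belongs to."""
    _require_int(side, "side")
    if not 1 <= side <= 8:
        raise DomainError(f"side must be in 1..8, got {side}")
    return (side + 1) // 2


def seconds_between(earlier: datetime, later: datetime) -> float:
    """Signed difference ``later - earlier`` in seconds, on the UTC axis."""
    return (later - earlier).total_seconds()


@dataclass(frozen=True)
class TimeInterval:
    """Half-open interval ``[start, end)`` between two aware timestamps."""

    start: datetime
    end: datetime

    def __post_init__(self) -> None:
        _require_aware(self.start, "TimeInterval.start")
        _require_aware(self.end, "TimeInterval.end")
        if self.start > self.end:
            raise DomainError(
                f"TimeInterval start {self.start!r} is after end {self.end!r}"
            )

    def __contains__(self, moment: datetime) -> bool:
        _require_aware(moment, "membership operand")
        return self.start <= moment < self.end

    def overlaps(self, other: "TimeInterval") -> bool:
        """True iff the two half-open intervals share at least one instant."""
        return self.start < other.end and other.start < self.end

    @property
    def duration(self) -> timedelta:
        return self.end - self.start

    @property
    def duration_seconds(self) -> float:
        return self.duration.total_seconds()


@dataclass(frozen=True)
class Animal:
    """One subject: display name, sex and RFID transponder tag(s).

    ``Tag`` is stored as a frozenset of transponder codes: a freshly loaded
    animal carries exactly one, but merging recording sessions may unify
    animals recorded under different transponders (e.g. after re-tagging).
    """

    Name: str
    Sex: str = "unknown"
    Tag: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.Name:
            raise DomainError("Animal.Name must be non-empty")
        if self.Sex not in SEXES:
            raise DomainError(
                f"Animal.Sex must be one of {SEXES}, got {self.Sex!r}"
            )
        tags = self.Tag
        if isinstance(tags, str):
            tags = frozenset({tags})
        else:
            tags = frozenset(str(t) for t in tags)
        if not tags or any(not t for t in tags):
            raise DomainError(f"Animal {self.Name!r} needs >=1 non-empty tag")
        object.__setattr__(self, "Tag", tags)


@dataclass(frozen=True)
class Group:
    """A named collection of animals (a cohort, a treatment arm, ...)."""

    Name: str
    Animals: tuple = ()

    def __post_init__(self) -> None:
        if not self.Name:
            raise DomainError("Group.Name must be non-empty")
        object.__setattr__(self, "Animals", tuple(self.Animals))


@dataclass(frozen=True)
class Nosepoke:
    """One nosepoke into a side opening during a visit.

    ``SideCondition`` is the experiment-design flag for the poked side:
    positive means the side was marked correct (rewarded / accessible) for
    this mouse, negative incorrect, zero no contingency in force.
    ``Visit`` is a back-link to the containing visit; it is excluded from
    equality and hashing to keep record comparison well-founded.
    """

    Start: datetime
    End: datetime
    Side: int
    SideCondition: int = 0
    LickNumber: int = 0
    LickDuration: float = 0.0
    Visit: Optional["Visit"] = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        _require_aware(self.Start, "Nosepoke.Start")
        _require_aware(self.End, "Nosepoke.End")
        if self.Start > self.End:
            raise DomainError("Nosepoke.Start must not be after Nosepoke.End")
        door_from_side(self.Side)  # validates range
        if self.SideCondition not in (-1, 0, 1):
            raise DomainError(
                f"Nosepoke.SideCondition must be -1, 0 or +1, got {self.SideCondition!r}"
            )
        if _require_int(self.LickNumber, "Nosepoke.LickNumber") < 0:
            raise DomainError("Nosepoke.LickNumber must be >= 0")
        if self.LickDuration < 0:
            raise DomainError("Nosepoke.LickDuration must be >= 0 seconds")

    @property
    def Door(self) -> str:
        """``"left"`` or ``"right"``, derived from :attr:`Side`."""
        return door_from_side(self.Side)

    @property
    def Corner(self) -> int:
        return corner_of_side(self.Side)

    @property
    def Duration(self) -> float:
        """Poke duration in seconds."""
        return seconds_between(self.Start, self.End)


@dataclass(frozen=True)
class Visit:
    """One corner entry of one mouse, with its nosepokes.

    ``CornerCondition`` flags whether the visited corner was the one marked
    correct for this mouse (positive), a wrong corner (negative), or no
    contingency (zero, e.g. free adaptation).  Contained nosepokes are stored
    ordered by their ``Start`` (stable for ties) and each carries a back-link
    to this visit.  Records that violate cross-field consistency (a nosepoke
    outside the visit's bounds, a side in another corner) are representable
    on purpose: the loader never filters, validation flags them instead.
    """

    Start: datetime
    End: datetime
    Cage: int
    Corner: int
    Animal: Animal
    CornerCondition: int = 0
    Nosepokes: tuple = ()

    def __post_init__(self) -> None:
        _require_aware(self.Start, "Visit.Start")
        _require_aware(self.End, "Visit.End")
        if self.Start > self.End:
            raise DomainError("Visit.Start must not be after Visit.End")
        if _require_int(self.Cage, "Visit.Cage") < 1:
            raise DomainError(f"Visit.Cage must be >= 1, got {self.Cage}")
        _require_int(self.Corner, "Visit.Corner")
        if not 1 <= self.Corner <= 4:
            raise DomainError(f"Visit.Corner must be in 1..4, got {self.Corner}")
        if self.CornerCondition not in (-1, 0, 1):
            raise DomainError(
                f"Visit.CornerCondition must be -1, 0 or +1, got {self.CornerCondition!r}"
            )
        ordered = sorted(self.Nosepokes, key=lambda n: n.Start)  # stable
        bound = []
        for poke in ordered:
            copy = dataclasses.replace(poke)
            object.__setattr__(copy, "Visit", self)
            bound.append(copy)
        object.__setattr__(self, "Nosepokes", tuple(bound))

    @property
    def Duration(self) -> float:
        """Visit duration in seconds."""
        return seconds_between(self.Start, self.End)

    @property
    def interval(self) -> TimeInterval:
        return TimeInterval(self.Start, self.End)

    def __iter__(self) -> Iterator[Nosepoke]:
        return iter(self.Nosepokes)


@dataclass(frozen=True)
class EnvironmentalConditions:
    """Periodic cage-environment sample: illumination (device units) and °C."""

    DateTime: datetime
    Cage: int
    Illumination: int = 0
    Temperature: float = 0.0

    def __post_init__(self) -> None:
        _require_aware(self.DateTime, "EnvironmentalConditions.DateTime")
        _require_int(self.Cage, "EnvironmentalConditions.Cage")
        if _require_int(self.Illumination, "EnvironmentalConditions.Illumination") < 0:
            raise DomainError("Illumination must be >= 0")


@dataclass(frozen=True)
class LogEntry:
    """One controller log line (info, warning or error)."""

    DateTime: datetime
    Category: str
    Type: str
    Cage: Optional[int] = None
    Corner: Optional[int] = None
    Side: Optional[int] = None
    Notes: str = ""

    def __post_init__(self) -> None:
        _require_aware(self.DateTime, "LogEntry.DateTime")
        if not self.Category or not self.Type:
            raise DomainError("LogEntry.Category and LogEntry.Type must be non-empty")


@dataclass(frozen=True)
class HardwareEvent:
    """A hardware state change (door, air valve, LED, ...)."""

    DateTime: datetime
    Cage: int
    Corner: int
    Type: str
    State: int
    Side: Optional[int] = None

    def __post_init__(self) -> None:
        _require_aware(self.DateTime, "HardwareEvent.DateTime")
        _require_int(self.Cage, "HardwareEvent.Cage")
        _require_int(self.Corner, "HardwareEvent.Corner")
        _require_int(self.State, "HardwareEvent.State")
        if not self.Type:
            raise DomainError("HardwareEvent.Type must be non-empty")


def sort_by_time(records: Sequence, attribute: str = "Start") -> tuple:
    """Stable sort of records by a datetime attribute; idempotent."""
    return tuple(sorted(records, key=lambda r: getattr(r, attribute)))
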