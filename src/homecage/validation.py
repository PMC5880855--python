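"""Automatic data quality control.

Two complementary mechanisms, both strictly *side-band*: they flag records
but never remove or repair them (the loaded record stream is authoritative
and unfiltered).

1. **Failure detection from the controller log.**  RFID presence failures
   and lickometer failures are reported by the cage controller as log
   entries (``Error``/``Presence`` and ``Warning``/``Lickometer`` in this
   dialect).  Around each such entry the affected corner (and side, for
   lickometer failures) is considered unreliable for a symmetric padding
   window (default one hour on each side); overlapping windows for the same
   location are coalesced into one :class:`ExcludedPeriod`.  The detector
   table is extensible: new failure classes are registered against a
   (category, type, scope) descriptor without touching this module.

2. **Structural integrity checks** over a whole dataset
   (:func:`check_integrity`): nosepokes outside their visit's bounds, side
   numbers inconsistent with the visited corner, two simultaneous visits in
   one corner (physically impossible: the corner admits one mouse at a
   time), visits outside the recorded session interval, and more distinct
   mice in one cage than it can house (16).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .errors import DomainError
from .archive import SessionData
from .model import LogEntry, TimeInterval, Visit, corner_of_side

__all__ = [
    "CAGE_CAPACITY",
    "DEFAULT_PAD_SECONDS",
    "ExcludedPeriod",
    "Finding",
    "DetectorSpec",
    "register_detector",
    "detect_failures",
    "detect_presence_errors",
    "detect_lickometer_warnings",
    "flag_affected",
    "check_integrity",
]

CAGE_CAPACITY = 16
DEFAULT_PAD_SECONDS = 3600.0


@dataclass(frozen=True)
class ExcludedPeriod:
    """A time window during which one location's data is unreliable."""

    interval: TimeInterval
    cage: int
    kind: str
    corner: Optional[int] = None
    side: Optional[int] = None
    source_entries: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "source_entries", tuple(self.source_entries))
        if not self.source_entries:
            raise DomainError("ExcludedPeriod needs >=1 source log entry")


@dataclass(frozen=True)
class DetectorSpec:
    """Descriptor matching log entries to a failure class.

    ``scope`` lists the location attributes (``"Cage"``, ``"Corner"``,
    ``"Side"``) that failure windows are keyed and coalesced by, and that
    must match for a record to be affected.
    """

    kind: str
    category: str
    type: str
    scope: Tuple[str, ...]


_DETECTORS: Dict[str, DetectorSpec] = {}


def register_detector(kind, category, type, scope) -> DetectorSpec:
    """Register a failure class; returns its spec.  Idempotent on re-register."""
    spec = DetectorSpec(kind=kind, category=category, type=type,
                        scope=tuple(scope))
    _DETECTORS[kind] = spec
    return spec


register_detector("PresenceError", "Error", "Presence", ("Cage", "Corner"))
register_detector("LickometerWarning", "Warning", "Lickometer",
                  ("Cage", "Corner", "Side"))


def detect_failures(
    log: Sequence[LogEntry],
    kind: str,
    pad: float = DEFAULT_PAD_SECONDS,
) -> List[ExcludedPeriod]:
    """Detect failure windows of a registered class from the log.

    Every matching log entry yields a window ``[t - pad, t + pad)`` scoped to
    its location; overlapping or touching windows for the same location are
    coalesced, carrying all contributing entries.
    """
    if kind not in _DETECTORS:
        raise DomainError(
            f"unknown detector {kind!r}; registered: {sorted(_DETECTORS)}"
        )
    if pad < 0:
        raise DomainError(f"pad must be >= 0 seconds, got {pad}")
    spec = _DETECTORS[kind]
    half = timedelta(seconds=pad)

    by_scope: Dict[tuple, list] = {}
    for entry in log:
        if entry.Category != spec.category or entry.Type != spec.type:
            continue
        key = tuple(getattr(entry, attr) for attr in spec.scope)
        by_scope.setdefault(key, []).append(entry)

    periods: List[ExcludedPeriod] = []
    for key, entries in by_scope.items():
        entries = sorted(entries, key=lambda e: e.DateTime)
        open_start = open_end = None
        contributing: list = []

        def close():
            scope_values = dict(zip(spec.scope, key))
            periods.append(
                ExcludedPeriod(
                    interval=TimeInterval(open_start, open_end),
                    cage=scope_values.get("Cage"),
                    corner=scope_values.get("Corner"),
                    side=scope_values.get("Side"),
                    kind=kind,
                    source_entries=tuple(contributing),
                )
            )

        for entry in entries:
            start, end = entry.DateTime - half, entry.DateTime + half
            if open_start is None:
                open_start, open_end = start, end
                contributing = [entry]
            elif start <= open_end:  # overlapping or touching: coalesce
                open_end = max(open_end, end)
                contributing.append(entry)
            else:
                close()
                open_start, open_end = start, end
                contributing = [entry]
        if open_start is not None:
            close()
    periods.sort(key=lambda p: (p.interval.start, p.cage,
                                p.corner or 0, p.side or 0))
    return periods


def detect_presence_errors(
    log: Sequence[LogEntry], pad: float = DEFAULT_PAD_SECONDS
) -> List[ExcludedPeriod]:
    """RFID presence failures: windows around ``Error``/``Presence`` entries."""
    return detect_failures(log, "PresenceError", pad)


def detect_lickometer_warnings(
    log: Sequence[LogEntry], pad: float = DEFAULT_PAD_SECONDS
) -> List[ExcludedPeriod]:
    """Lickometer failures: windows around ``Warning``/``Lickometer`` entries."""
    return detect_failures(log, "LickometerWarning", pad)


def _overlap(start_a, end_a, start_b, end_b) -> bool:
    return start_a < end_b and start_b < end_a


def flag_affected(
    visits: Sequence[Visit],
    excluded: Sequence[ExcludedPeriod],
) -> Mapping[Visit, Set[ExcludedPeriod]]:
    """Map every visit to the excluded periods that cast doubt on it.

    A presence-failure period affects a visit iff the visit is in the same
    cage and corner and its ``[Start, End)`` overlaps the period.  A
    lickometer period affects a visit iff any of its nosepokes was made to
    the period's side (same cage) and overlaps the period in time.  Visits
    are never removed: an unaffected visit maps to an empty set.
    """
    flags: Dict[Visit, Set[ExcludedPeriod]] = {v: set() for v in visits}
    for period in excluded:
        ps, pe = period.interval.start, period.interval.end
        for visit in visits:
            if period.side is not None:
                if visit.Cage != period.cage:
                    continue
                for poke in visit.Nosepokes:
                    if poke.Side == period.side and _overlap(
                        poke.Start, poke.End, ps, pe
                    ):
                        flags[visit].add(period)
                        break
            else:
                if (
                    visit.Cage == period.cage
                    and visit.Corner == period.corner
                    and _overlap(visit.Start, visit.End, ps, pe)
                ):
                    flags[visit].add(period)
    return flags


@dataclass(frozen=True)
class Finding:
    """One structural inconsistency discovered by :func:`check_integrity`."""

    kind: str
    message: str
    cage: Optional[int] = None
    corner: Optional[int] = None
    side: Optional[int] = None
    animal: Optional[str] = None


def check_integrity(data: SessionData) -> List[Finding]:
    """Report (never correct) structural inconsistencies in a dataset."""
    findings: List[Finding] = []

    for visit in data.visits:
        for poke in visit.Nosepokes:
            if poke.Start < visit.Start or poke.End > visit.End:
                findings.append(
                    Finding(
                        kind="nosepoke_outside_visit",
                        message=(
                            f"nosepoke [{poke.Start} .. {poke.End}) outside "
                            f"its visit's bounds [{visit.Start} .. {visit.End})"
                        ),
                        cage=visit.Cage,
                        corner=visit.Corner,
                        side=poke.Side,
                        animal=visit.Animal.Name,
                    )
                )
            if corner_of_side(poke.Side) != visit.Corner:
                findings.append(
                    Finding(
                        kind="side_corner_mismatch",
                        message=(
                            f"nosepoke side {poke.Side} belongs to corner "
                            f"{corner_of_side(poke.Side)}, not the visited "
                            f"corner {visit.Corner}"
                        ),
                        cage=visit.Cage,
                        corner=visit.Corner,
                        side=poke.Side,
                        animal=visit.Animal.Name,
                    )
                )
        if (
            visit.Start < data.session_interval.start
            or visit.End > data.session_interval.end
        ):
            findings.append(
                Finding(
                    kind="visit_outside_session",
                    message=(
                        f"visit [{visit.Start} .. {visit.End}) outside the "
                        f"session interval"
                    ),
                    cage=visit.Cage,
                    corner=visit.Corner,
                    animal=visit.Animal.Name,
                )
            )

    # one corner admits one mouse at a time: overlapping visits are impossible
    by_location: Dict[tuple, list] = {}
    for visit in data.visits:
        by_location.setdefault((visit.Cage, visit.Corner), []).append(visit)
    for (cage, corner), located in by_location.items():
        located = sorted(located, key=lambda v: v.Start)
        for previous, current in zip(located, located[1:]):
            if current.Start < previous.End:
                findings.append(
                    Finding(
                        kind="overlapping_visits",
                        message=(
                            f"visits of {previous.Animal.Name!r} and "
                            f"{current.Animal.Name!r} overlap in cage {cage} "
                            f"corner {corner} at {current.Start}"
                        ),
                        cage=cage,
                        corner=corner,
                    )
                )

    mice_per_cage: Dict[int, set] = {}
    for visit in data.visits:
        mice_per_cage.setdefault(visit.Cage, set()).add(visit.Animal.Name)
    for cage, mice in sorted(mice_per_cage.items()):
        if len(mice) > CAGE_CAPACITY:
            findings.append(
                Finding(
                    kind="cage_overcapacity",
                    message=(
                        f"{len(mice)} distinct mice recorded in cage {cage}; "
                        f"a cage houses at most {CAGE_CAPACITY}"
                    ),
                    cage=cage,
                )
            )
    return findings
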