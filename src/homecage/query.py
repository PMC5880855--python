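"""Selection API over a loaded dataset.

All selectors are pure functions on :class:`~homecage.archive.SessionData` /
:class:`~homecage.archive.DataSet` and never mutate or filter the underlying
data beyond what the caller asks for.  Time filtering is half-open
(``start <= t < end``) and, for visits, judged on the visit's ``Start`` by
default; overlap-based selection is available via ``select="overlap"``.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Set, Union

from .errors import DomainError, RecordLookupError
from .archive import SessionData
from .model import (
    Animal,
    EnvironmentalConditions,
    Group,
    HardwareEvent,
    LogEntry,
    TimeInterval,
    Visit,
)

__all__ = [
    "get_visits",
    "get_animal",
    "get_group",
    "get_log",
    "get_environment",
    "get_hardware_events",
]

_ORDER_FIELDS = ("Start", "End")


def _resolve_mice(data: SessionData, mice) -> Optional[Set[str]]:
    if mice is None:
        return None
    names = {mice} if isinstance(mice, str) else set(mice)
    unknown = sorted(names - set(data.animals))
    if unknown:
        raise RecordLookupError(
            f"unknown animal name(s) {unknown}; known animals: "
            f"{sorted(data.animals)}"
        )
    return names


def get_visits(
    data: SessionData,
    mice: Union[str, Iterable[str], None] = None,
    interval: Optional[TimeInterval] = None,
    order: Optional[str] = None,
    select: str = "start",
) -> Sequence[Visit]:
    """Select visits by animal and time.

    Parameters
    ----------
    mice:
        A name or collection of animal names; ``None`` selects all animals.
        Unknown names raise a lookup error.
    interval:
        Half-open time window.  With the default ``select="start"`` a visit
        is selected iff its ``Start`` lies in the window; ``select="overlap"``
        selects visits whose ``[Start, End)`` intersects the window.
    order:
        ``"Start"``, ``"End"`` or ``None``.  Sorting is stable, so ties keep
        their stored (chronological/source) order.
    """
    names = _resolve_mice(data, mice)
    if order is not None and order not in _ORDER_FIELDS:
        raise DomainError(
            f"order must be one of {_ORDER_FIELDS} or None, got {order!r}"
        )
    if select not in ("start", "overlap"):
        raise DomainError(f"select must be 'start' or 'overlap', got {select!r}")

    result = list(data.visits)
    if names is not None:
        result = [v for v in result if v.Animal.Name in names]
    if interval is not None:
        if select == "start":
            result = [v for v in result if v.Start in interval]
        else:
            result = [v for v in result if v.interval.overlaps(interval)]
    if order is not None:
        result.sort(key=lambda v: getattr(v, order))  # stable
    return result


def get_animal(data: SessionData, name: str) -> Animal:
    """Look up one animal by name (case-sensitive)."""
    try:
        return data.animals[name]
    except KeyError:
        raise RecordLookupError(
            f"unknown animal {name!r}; known animals: {sorted(data.animals)}"
        ) from None


def get_group(data: SessionData, name: str) -> Group:
    """Look up one group by name (case-sensitive)."""
    try:
        return data.groups[name]
    except KeyError:
        raise RecordLookupError(
            f"unknown group {name!r}; known groups: {sorted(data.groups)}"
        ) from None


def _time_filtered(records, interval: Optional[TimeInterval]):
    if interval is None:
        return list(records)
    return [r for r in records if r.DateTime in interval]


def get_log(
    data: SessionData, interval: Optional[TimeInterval] = None
) -> Sequence[LogEntry]:
    """Log entries whose timestamp falls in the half-open interval."""
    return _time_filtered(data.log, interval)


def get_environment(
    data: SessionData, interval: Optional[TimeInterval] = None
) -> Sequence[EnvironmentalConditions]:
    """Environment samples whose timestamp falls in the half-open interval."""
    return _time_filtered(data.environment, interval)


def get_hardware_events(
    data: SessionData, interval: Optional[TimeInterval] = None
) -> Sequence[HardwareEvent]:
    """Hardware events whose timestamp falls in the half-open interval."""
    return _time_filtered(data.hardware, interval)
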