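"""Behavioral measures computed from visit/nosepoke events.

Four families of analyses are provided:

* **First-nosepoke side counts** — how often the first poke of a visit went
  to the left vs. the right door of the corner.
* **Discrimination performance** — among visits to the corner marked correct
  for the mouse, the fraction whose *first* nosepoke went to the side marked
  correct.  This is the standard readout of two-bottle discrimination
  learning (reward vs. neutral bottle in the same corner).
* **Corner (place) preference** — the fraction of all visits that went to
  the corner marked correct; chance level with four corners and no learning
  is 25 %.
* **Inter-visit intervals** — gaps between consecutive visits to the same
  corner of the same cage, pooled over mice: a proxy for corner vacancy and
  the group's social dynamics, histogrammed on a logarithmic axis.

Performance values are fractions in ``[0, 1]``; a slice with an empty
denominator yields ``None`` (scalar form) or ``NaN`` (matrix form) rather
than zero, so cohort averages are taken only over defined cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import DomainError
from .archive import SessionData
from .model import LEFT, RIGHT, Visit, seconds_between
from .query import get_group, get_visits
from .timeline import Timeline

_range = range  # several APIs take a `range=(lo, hi)` argument

__all__ = [
    "PerformanceMatrix",
    "LogHistogram",
    "first_nosepoke_side_counts",
    "discrimination_performance",
    "corner_preference_performance",
    "performance_matrix",
    "intervisit_intervals",
    "log_histogram",
    "intervals_to_frame",
]


def first_nosepoke_side_counts(visits: Sequence[Visit]) -> Dict[str, int]:
    """Count visits by the door of their first nosepoke.

    Visits without any nosepoke are skipped; for the rest the first poke is
    the one with minimal ``Start`` (ties resolved by stored order).  The two
    counts sum to the number of visits having at least one nosepoke.
    """
    counts = {LEFT: 0, RIGHT: 0}
    for visit in visits:
        if visit.Nosepokes:
            counts[visit.Nosepokes[0].Door] += 1
    return counts


def discrimination_performance(visits: Sequence[Visit]) -> Optional[float]:
    """Fraction of correct-corner visits whose first poke hit the correct side.

    Only visits with ``CornerCondition > 0`` and at least one nosepoke enter
    the denominator; the numerator counts those whose first nosepoke has
    ``SideCondition > 0``.  Returns ``None`` when the denominator is empty.
    """
    hits = total = 0
    for visit in visits:
        if visit.CornerCondition > 0 and visit.Nosepokes:
            total += 1
            if visit.Nosepokes[0].SideCondition > 0:
                hits += 1
    return hits / total if total else None


def corner_preference_performance(visits: Sequence[Visit]) -> Optional[float]:
    """Fraction of all visits made to the corner marked correct.

    Returns ``None`` for an empty visit sequence.  With four corners and no
    reward contingency the expected value is the 25 % chance level.
    """
    if not visits:
        return None
    hits = sum(1 for v in visits if v.CornerCondition > 0)
    return hits / len(visits)


_MODES = {
    "discrimination": discrimination_performance,
    "corner_preference": corner_preference_performance,
}


def _denominator(visits: Sequence[Visit], mode: str) -> int:
    if mode == "discrimination":
        return sum(1 for v in visits if v.CornerCondition > 0 and v.Nosepokes)
    return len(visits)


@dataclass(frozen=True)
class PerformanceMatrix:
    """Mice × phases performance values with parallel denominators.

    ``values`` holds fractions in ``[0, 1]`` with ``NaN`` for undefined
    cells (denominator zero); ``counts`` holds the denominators.  Cohort
    summaries (column means, SEM) skip undefined cells.
    """

    values: pd.DataFrame
    counts: pd.DataFrame
    mode: str

    @property
    def mice(self) -> Tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def phases(self) -> Tuple[str, ...]:
        return tuple(self.values.columns)

    def column_means(self) -> pd.Series:
        """Per-phase mean over mice with a defined value."""
        return self.values.mean(axis=0, skipna=True)

    def column_sem(self) -> pd.Series:
        """Per-phase standard error of the mean across mice."""
        return self.values.sem(axis=0, skipna=True, ddof=1)

    def to_tidy(self) -> pd.DataFrame:
        """One row per mouse × phase: ``mouse, phase, performance, n``."""
        rows = []
        for mouse in self.values.index:
            for phase in self.values.columns:
                value = self.values.at[mouse, phase]
                rows.append(
                    {
                        "mouse": mouse,
                        "phase": phase,
                        "performance": value,
                        "n": int(self.counts.at[mouse, phase]),
                    }
                )
        return pd.DataFrame(rows, columns=["mouse", "phase", "performance", "n"])

    def to_csv(self, path_or_buffer) -> None:
        """Export the tidy form as CSV."""
        self.to_tidy().to_csv(path_or_buffer, index=False)


def performance_matrix(
    data: SessionData,
    timeline: Timeline,
    phases: Sequence[str],
    subjects: Union[str, Iterable[str], None] = None,
    mode: str = "discrimination",
) -> PerformanceMatrix:
    """Per-mouse, per-phase performance table.

    ``subjects`` may be a group name (resolved against the dataset's
    groups), an explicit collection of animal names, or ``None`` for every
    animal in the dataset.  Cell ``(m, p)`` is the chosen performance over
    the visits of mouse ``m`` whose start falls inside phase ``p``.
    """
    if mode not in _MODES:
        raise DomainError(f"mode must be one of {sorted(_MODES)}, got {mode!r}")
    metric = _MODES[mode]

    if subjects is None:
        mice = list(data.animals)
    elif isinstance(subjects, str):
        mice = [animal.Name for animal in get_group(data, subjects).Animals]
    else:
        mice = list(subjects)

    values = pd.DataFrame(
        np.nan, index=pd.Index(mice, name="mouse"),
        columns=pd.Index(list(phases), name="phase"), dtype=float,
    )
    counts = pd.DataFrame(
        0, index=values.index, columns=values.columns, dtype=int,
    )
    for phase in phases:
        bounds = timeline.bounds(phase)
        for mouse in mice:
            visits = get_visits(data, {mouse}, bounds)
            value = metric(visits)
            if value is not None:
                values.at[mouse, phase] = value
            counts.at[mouse, phase] = _denominator(visits, mode)
    return PerformanceMatrix(values=values, counts=counts, mode=mode)


def intervisit_intervals(
    visits: Sequence[Visit],
    gap: str = "end_to_start",
) -> Dict[Tuple[int, int], List[float]]:
    """Gaps (seconds) between consecutive visits to each cage corner.

    Visits are ordered by ``Start`` and partitioned by ``(Cage, Corner)``
    preserving that order; mice are pooled, so the gaps measure corner
    traffic, not per-mouse pacing.  With the default ``gap="end_to_start"``
    each gap runs from one visit's ``End`` to the next visit's ``Start``
    (how long the corner stood empty); ``gap="start_to_start"`` measures
    onset-to-onset spacing instead.  Negative values (overlap anomalies)
    are reported, never dropped.  A corner with ``k`` visits yields
    ``k - 1`` gaps.
    """
    if gap not in ("end_to_start", "start_to_start"):
        raise DomainError(
            f"gap must be 'end_to_start' or 'start_to_start', got {gap!r}"
        )
    ordered = sorted(visits, key=lambda v: v.Start)  # stable
    partitions: Dict[Tuple[int, int], List[Visit]] = {}
    for visit in ordered:
        partitions.setdefault((visit.Cage, visit.Corner), []).append(visit)
    intervals: Dict[Tuple[int, int], List[float]] = {}
    for key, located in partitions.items():
        gaps = []
        for previous, current in zip(located, located[1:]):
            anchor = previous.End if gap == "end_to_start" else previous.Start
            gaps.append(seconds_between(anchor, current.Start))
        intervals[key] = gaps
    return intervals


@dataclass(frozen=True)
class LogHistogram:
    """Histogram over bins equally spaced on a logarithmic axis.

    ``bins`` are half-open ``[lo_k, hi_k)`` second ranges; ``counts`` the
    per-bin tallies; ``anomalies`` counts non-positive inputs (overlap
    artifacts), which cannot be placed on a log axis; ``out_of_range``
    counts positive inputs outside ``[lo, hi)``.
    """

    bins: Tuple[Tuple[float, float], ...]
    counts: Tuple[int, ...]
    anomalies: int
    out_of_range: int

    def __iter__(self):
        return iter(zip(self.bins, self.counts))

    @property
    def total(self) -> int:
        return sum(self.counts)


def log_histogram(
    intervals: Iterable[float],
    bins_per_decade: int = 8,
    range: Tuple[float, float] = (1.0, 100000.0),
) -> LogHistogram:
    """Histogram interval durations into log-spaced bins.

    Bin edges are ``lo * 10**(k / bins_per_decade)``; the last bin is
    truncated at ``hi`` if needed.  Bins are half-open, so a value equal to
    an edge falls into the bin starting there.
    """
    lo, hi = range
    if lo <= 0:
        raise DomainError(f"histogram range must start above 0, got {lo}")
    if hi <= lo:
        raise DomainError(f"histogram range must satisfy lo < hi, got {range}")
    if bins_per_decade < 1:
        raise DomainError(f"bins_per_decade must be >= 1, got {bins_per_decade}")

    n_bins = math.ceil(bins_per_decade * math.log10(hi / lo) - 1e-9)
    edges = [lo * 10 ** (k / bins_per_decade) for k in _range(n_bins)]
    edges.append(hi)
    edges = np.asarray(edges)

    values = np.asarray(list(intervals), dtype=float)
    anomalies = int(np.count_nonzero(values <= 0))
    positive = values[values > 0]
    in_range = positive[(positive >= lo) & (positive < hi)]
    out_of_range = positive.size - in_range.size
    counts = np.zeros(n_bins, dtype=int)
    if in_range.size:
        indices = np.searchsorted(edges, in_range, side="right") - 1
        np.add.at(counts, indices, 1)

    bins = tuple(
        (float(edges[k]), float(edges[k + 1])) for k in _range(n_bins)
    )
    return LogHistogram(
        bins=bins,
        counts=tuple(int(c) for c in counts),
        anomalies=anomalies,
        out_of_range=int(out_of_range),
    )


def intervals_to_frame(
    intervals: Mapping[Tuple[int, int], Sequence[float]],
    bins_per_decade: int = 8,
    range: Tuple[float, float] = (1.0, 100000.0),
) -> pd.DataFrame:
    """Tidy per-corner log-histogram: ``cage, corner, bin_start_s, bin_end_s, count``."""
    rows = []
    for (cage, corner) in sorted(intervals):
        histogram = log_histogram(intervals[(cage, corner)], bins_per_decade, range)
        for (lo, hi), count in histogram:
            rows.append(
                {
                    "cage": cage,
                    "corner": corner,
                    "kind": "bin",
                    "bin_start_s": lo,
                    "bin_end_s": hi,
                    "count": count,
                }
            )
        rows.append(
            {
                "cage": cage,
                "corner": corner,
                "kind": "nonpositive",
                "bin_start_s": np.nan,
                "bin_end_s": np.nan,
                "count": histogram.anomalies,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cage", "corner", "kind", "bin_start_s", "bin_end_s", "count"],
    )
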