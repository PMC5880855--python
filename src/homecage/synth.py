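"""Synthetic multi-phase cage experiments with known ground truth.

The generator emulates the standard corner-learning protocols run in
automated group-housing cages: an experiment is a sequence of named 12-hour
phases (nosepoke adaptation, then place-preference / discrimination
learning), each with a programmed probability that a visit goes to the
mouse's rewarded corner (``p_corner``) and that a nosepoke within the
rewarded corner goes to the rewarded side (``p_side``).  Mice are assigned
rewarded corners round-robin, spreading them over corners as evenly as
possible; rewarded sides alternate left/right.

Per mouse and phase, visit onsets follow a homogeneous Poisson process at
the configured rate and visit durations are log-normal (median ~10 s by
default).  Corner exclusivity is physical — one mouse per corner at a time —
so colliding visits are shifted to start 1 ms after the earlier visit ends;
a configuration so dense that a shift would exceed one hour is rejected as
infeasible.  Nosepoke counts per visit are Poisson, lick counts Poisson per
poke.  Hardware failures (RFID presence errors, lickometer warnings) can be
injected at chosen times and locations; they are written into the session
log exactly as the controller would report them, and recorded in the
returned :class:`GroundTruth` together with the visits they affect.

Everything is reproducible: the same config and seed give byte-identical
archives.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import yaml
from zoneinfo import ZoneInfo

from .errors import DomainError, GenerationError
from .archive import SessionData
from .model import (
    LEFT,
    Animal,
    EnvironmentalConditions,
    Group,
    HardwareEvent,
    LogEntry,
    Nosepoke,
    TimeInterval,
    Visit,
)
from .timeline import Phase, Timeline, localize
from .validation import CAGE_CAPACITY

__all__ = [
    "PhaseSpec",
    "FailureSpec",
    "ExperimentConfig",
    "GroundTruth",
    "default_phases",
    "generate_experiment",
    "partition_records",
]

_MS = timedelta(milliseconds=1)


@dataclass(frozen=True)
class PhaseSpec:
    """One experiment phase and its programmed behavioral statistics.

    ``p_corner`` is the probability that a visit goes to the mouse's
    rewarded corner (the remaining mass is uniform over the other three);
    ``p_side`` the probability that a poke inside the rewarded corner goes
    to the rewarded side.  ``mark_conditions=False`` models free-adaptation
    phases where no contingency is in force: corner/side condition flags
    are written as 0.  ``visit_rate`` (visits/mouse/hour) overrides the
    config-wide default when set.
    """

    name: str
    duration_hours: float = 12.0
    dark: bool = True
    p_corner: float = 0.25
    p_side: float = 0.5
    mark_conditions: bool = True
    visit_rate: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise DomainError("phase name must be non-empty")
        if self.duration_hours <= 0:
            raise DomainError(f"phase {self.name!r}: duration must be > 0 h")
        for label, p in (("p_corner", self.p_corner), ("p_side", self.p_side)):
            if not 0.0 <= p <= 1.0:
                raise DomainError(f"phase {self.name!r}: {label} must be in [0, 1]")
        if self.visit_rate is not None and self.visit_rate < 0:
            raise DomainError(f"phase {self.name!r}: visit_rate must be >= 0")


@dataclass(frozen=True)
class FailureSpec:
    """One injected hardware failure.

    ``kind`` is ``"presence"`` (RFID detection failure, scoped to a corner)
    or ``"lickometer"`` (lick sensor failure, scoped to a side).
    ``at_hours`` is the failure time as an offset from experiment start.
    """

    kind: str
    cage: int
    corner: int
    at_hours: float
    side: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("presence", "lickometer"):
            raise DomainError(
                f"failure kind must be 'presence' or 'lickometer', got {self.kind!r}"
            )
        if self.kind == "lickometer" and self.side is None:
            raise DomainError("lickometer failures must name a side")


def default_phases() -> Tuple[PhaseSpec, ...]:
    """The standard 6 × 12 h protocol: two adaptation phases at chance
    corner preference, then four place-preference phases with the rewarded
    corner increasingly preferred."""
    ramp = [
        ("NPA 1 dark", 0.25, 0.50),
        ("NPA 2 dark", 0.25, 0.50),
        ("Place Pref 1 dark", 0.55, 0.55),
        ("Place Pref 2 dark", 0.65, 0.65),
        ("Place Pref 3 dark", 0.75, 0.75),
        ("Place Pref 4 dark", 0.80, 0.80),
    ]
    return tuple(
        PhaseSpec(name=name, p_corner=pc, p_side=ps) for name, pc, ps in ramp
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """Complete description of a synthetic experiment.

    Defaults model a single-cage cohort of 12 mice running the standard
    6 × 12 h protocol at ~40 visits per mouse per phase (rate 10/3 per
    hour).  Mice are named ``M01``, ``M02``, ... unless ``mouse_names`` is
    given, and split into two equal cohorts ``C57A`` / ``C57B`` unless
    ``groups`` is given.
    """

    n_mice: int = 12
    n_cages: int = 1
    mouse_names: Optional[Tuple[str, ...]] = None
    groups: Optional[Mapping[str, Tuple[str, ...]]] = None
    phases: Tuple[PhaseSpec, ...] = field(default_factory=default_phases)
    start: str = "2012-08-01 12:00"
    tzinfo: str = "Etc/GMT-2"
    visit_rate: float = 10.0 / 3.0
    visit_duration_median_s: float = 10.0
    visit_duration_sigma: float = 0.8
    nosepoke_mean: float = 2.0
    lick_mean: float = 6.0
    lick_second_per_lick: float = 0.12
    env_sample_minutes: int = 60
    failures: Tuple[FailureSpec, ...] = ()
    failure_pad_s: float = 3600.0
    n_sessions: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "phases", tuple(self.phases))
        object.__setattr__(self, "failures", tuple(self.failures))
        if self.mouse_names is not None:
            names = tuple(self.mouse_names)
            if len(names) != self.n_mice or len(set(names)) != len(names):
                raise DomainError(
                    "mouse_names must hold n_mice distinct names"
                )
            object.__setattr__(self, "mouse_names", names)
        if self.groups is not None:
            object.__setattr__(
                self,
                "groups",
                {name: tuple(members) for name, members in self.groups.items()},
            )
        if self.n_mice < 1 or self.n_cages < 1:
            raise DomainError("need >= 1 mouse and >= 1 cage")
        if math.ceil(self.n_mice / self.n_cages) > CAGE_CAPACITY:
            raise DomainError(
                f"{self.n_mice} mice in {self.n_cages} cage(s) exceeds the "
                f"capacity of {CAGE_CAPACITY} mice per cage"
            )
        if not self.phases:
            raise DomainError("need >= 1 phase")
        if self.visit_rate < 0:
            raise DomainError("visit_rate must be >= 0")
        if self.n_sessions < 1:
            raise DomainError("n_sessions must be >= 1")
        if self.failure_pad_s < 0:
            raise DomainError("failure_pad_s must be >= 0")

    # -- names / assignments -------------------------------------------------

    def roster(self) -> Tuple[str, ...]:
        if self.mouse_names is not None:
            return self.mouse_names
        width = max(2, len(str(self.n_mice)))
        return tuple(f"M{i + 1:0{width}d}" for i in range(self.n_mice))

    def group_map(self) -> Mapping[str, Tuple[str, ...]]:
        if self.groups is not None:
            return self.groups
        names = self.roster()
        half = (len(names) + 1) // 2
        return {"C57A": names[:half], "C57B": names[half:]}

    # -- YAML round trip -----------------------------------------------------

    def to_dict(self) -> dict:
        raw = dataclasses.asdict(self)
        raw["phases"] = [dataclasses.asdict(p) for p in self.phases]
        raw["failures"] = [dataclasses.asdict(f) for f in self.failures]
        if self.mouse_names is not None:
            raw["mouse_names"] = list(self.mouse_names)
        if self.groups is not None:
            raw["groups"] = {k: list(v) for k, v in self.groups.items()}
        return raw

    @classmethod
    def from_dict(cls, raw: Mapping) -> "ExperimentConfig":
        raw = dict(raw)
        if "phases" in raw:
            raw["phases"] = tuple(
                p if isinstance(p, PhaseSpec) else PhaseSpec(**p)
                for p in raw["phases"]
            )
        if "failures" in raw:
            raw["failures"] = tuple(
                f if isinstance(f, FailureSpec) else FailureSpec(**f)
                for f in raw["failures"]
            )
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise DomainError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path, "r", encoding="utf-8") as handle:
            raw = yaml.safe_load(handle)
        return cls.from_dict(raw or {})


@dataclass(frozen=True)
class InjectedFailure:
    """Ground-truth record of one injected failure."""

    spec: FailureSpec
    time: datetime
    padded_interval: TimeInterval
    affected_visits: Tuple[Tuple[str, str], ...]  # (mouse name, Start isoformat)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually programmed, for use as a test oracle."""

    rewarded_corner: Mapping[str, int]
    rewarded_side: Mapping[str, int]
    cage_of: Mapping[str, int]
    phase_probabilities: Mapping[str, Tuple[float, float]]
    failures: Tuple[InjectedFailure, ...]
    total_visits: int


class _VisitDraft:
    __slots__ = ("mouse", "cage", "corner", "start_ms", "end_ms",
                 "condition", "pokes")

    def __init__(self, mouse, cage, corner, start_ms, end_ms, condition, pokes):
        self.mouse = mouse
        self.cage = cage
        self.corner = corner
        self.start_ms = start_ms
        self.end_ms = end_ms
        self.condition = condition
        self.pokes = pokes  # (offset_ms, dur_ms, side, condition, licks)


def _side_of(corner: int, door: str) -> int:
    return (corner - 1) * 2 + (1 if door == LEFT else 2)


def generate_experiment(
    config: ExperimentConfig,
) -> Tuple[List[SessionData], Timeline, GroundTruth]:
    """Generate a complete experiment: session archives, timeline, truth.

    Returns ``config.n_sessions`` sessions that together cover the whole
    experiment (records assigned to sessions by time), the phase timeline,
    and the ground truth needed to verify any analysis of the output.
    """
    rng = np.random.default_rng(config.seed)
    zone = ZoneInfo(config.tzinfo)
    t0 = localize(datetime.strptime(config.start, "%Y-%m-%d %H:%M"), zone)
    t0_utc = t0.astimezone(timezone.utc)

    def at_ms(offset_ms: int) -> datetime:
        return (t0_utc + offset_ms * _MS).astimezone(zone)

    names = config.roster()
    cage_of = {name: (i % config.n_cages) + 1 for i, name in enumerate(names)}
    # round-robin corner assignment within each cage, as even as possible
    per_cage_counter: Dict[int, int] = {}
    rewarded_corner: Dict[str, int] = {}
    rewarded_side: Dict[str, int] = {}
    for i, name in enumerate(names):
        cage = cage_of[name]
        k = per_cage_counter.get(cage, 0)
        per_cage_counter[cage] = k + 1
        corner = (k % 4) + 1
        rewarded_corner[name] = corner
        rewarded_side[name] = _side_of(corner, LEFT if i % 2 == 0 else "right")

    animals = {
        name: Animal(
            Name=name,
            Sex="female" if i % 2 == 0 else "male",
            Tag=frozenset({f"981{config.seed % 1000:03d}{i + 1:09d}"}),
        )
        for i, name in enumerate(names)
    }
    groups = {
        gname: Group(Name=gname, Animals=tuple(animals[m] for m in members))
        for gname, members in config.group_map().items()
    }

    # --- timeline ---------------------------------------------------------
    phase_objects = []
    phase_windows = []  # (spec, start_ms, end_ms)
    cursor_ms = 0
    for spec in config.phases:
        duration_ms = int(round(spec.duration_hours * 3600_000))
        phase_objects.append(
            Phase(
                name=spec.name,
                interval=TimeInterval(at_ms(cursor_ms), at_ms(cursor_ms + duration_ms)),
            )
        )
        phase_windows.append((spec, cursor_ms, cursor_ms + duration_ms))
        cursor_ms += duration_ms
    timeline = Timeline(phase_objects)
    experiment_end_ms = cursor_ms

    # --- visits -----------------------------------------------------------
    mu = math.log(config.visit_duration_median_s)
    drafts: List[_VisitDraft] = []
    for spec, window_start, window_end in phase_windows:
        rate = config.visit_rate if spec.visit_rate is None else spec.visit_rate
        window_s = (window_end - window_start) / 1000.0
        for index, name in enumerate(names):
            n_visits = int(rng.poisson(rate * window_s / 3600.0))
            if n_visits == 0:
                continue
            onsets = np.sort(rng.uniform(0.0, window_s, n_visits))
            durations = rng.lognormal(mu, config.visit_duration_sigma, n_visits)
            corner_draws = rng.random(n_visits)
            other_draws = rng.integers(0, 3, n_visits)
            poke_counts = rng.poisson(config.nosepoke_mean, n_visits)
            target = rewarded_corner[name]
            target_side = rewarded_side[name]
            for v in range(n_visits):
                if corner_draws[v] < spec.p_corner:
                    corner = target
                else:
                    others = [c for c in (1, 2, 3, 4) if c != target]
                    corner = others[other_draws[v]]
                condition = 0
                if spec.mark_conditions:
                    condition = 1 if corner == target else -1
                start_ms = window_start + int(round(onsets[v] * 1000))
                dur_ms = max(1, int(round(durations[v] * 1000)))
                pokes = []
                n_pokes = int(poke_counts[v])
                if n_pokes:
                    offsets = np.sort(rng.uniform(0.0, dur_ms, n_pokes))
                    for p in range(n_pokes):
                        offset = int(round(offsets[p]))
                        poke_dur = min(
                            dur_ms - offset,
                            max(1, int(round(rng.exponential(1.5) * 1000))),
                        )
                        if corner == target:
                            hit = rng.random() < spec.p_side
                            side = target_side if hit else (
                                _side_of(corner, LEFT)
                                if target_side % 2 == 0
                                else _side_of(corner, "right")
                            )
                        else:
                            side = _side_of(
                                corner, LEFT if rng.random() < 0.5 else "right"
                            )
                        poke_condition = 0
                        if spec.mark_conditions:
                            poke_condition = 1 if side == target_side else -1
                        licks = int(
                            rng.poisson(
                                config.lick_mean
                                if side == target_side
                                else config.lick_mean / 3.0
                            )
                        )
                        pokes.append((offset, poke_dur, side, poke_condition, licks))
                drafts.append(
                    _VisitDraft(
                        mouse=name,
                        cage=cage_of[name],
                        corner=corner,
                        start_ms=start_ms,
                        end_ms=start_ms + dur_ms,
                        condition=condition,
                        pokes=pokes,
                    )
                )

    _resolve_collisions(drafts, experiment_end_ms)

    visits = []
    for draft in sorted(drafts, key=lambda d: (d.start_ms, d.mouse)):
        pokes = tuple(
            Nosepoke(
                Start=at_ms(draft.start_ms + offset),
                End=at_ms(draft.start_ms + offset + dur),
                Side=side,
                SideCondition=condition,
                LickNumber=licks,
                LickDuration=round(licks * config.lick_second_per_lick, 3),
            )
            for offset, dur, side, condition, licks in draft.pokes
        )
        visits.append(
            Visit(
                Start=at_ms(draft.start_ms),
                End=at_ms(draft.end_ms),
                Cage=draft.cage,
                Corner=draft.corner,
                Animal=animals[draft.mouse],
                CornerCondition=draft.condition,
                Nosepokes=pokes,
            )
        )

    # --- environment samples ----------------------------------------------
    environment = []
    step_ms = config.env_sample_minutes * 60_000
    sample_ms = 0
    while sample_ms < experiment_end_ms:
        dark = True
        for spec, window_start, window_end in phase_windows:
            if window_start <= sample_ms < window_end:
                dark = spec.dark
                break
        for cage in range(1, config.n_cages + 1):
            environment.append(
                EnvironmentalConditions(
                    DateTime=at_ms(sample_ms),
                    Cage=cage,
                    Illumination=0 if dark else 100,
                    Temperature=round(22.0 + float(rng.normal(0.0, 0.3)), 1),
                )
            )
        sample_ms += step_ms

    # --- log & hardware events ----------------------------------------------
    log = [
        LogEntry(
            DateTime=at_ms(0),
            Category="Info",
            Type="Application",
            Notes="experiment started",
        ),
        LogEntry(
            DateTime=at_ms(experiment_end_ms),
            Category="Info",
            Type="Application",
            Notes="experiment finished",
        ),
    ]
    hardware = []
    for spec, window_start, _ in phase_windows:
        for cage in range(1, config.n_cages + 1):
            hardware.append(
                HardwareEvent(
                    DateTime=at_ms(window_start),
                    Cage=cage,
                    Corner=1,
                    Type="LED",
                    State=0 if spec.dark else 1,
                )
            )

    failures = []
    pad = timedelta(seconds=config.failure_pad_s)
    for spec in config.failures:
        moment = at_ms(int(round(spec.at_hours * 3600_000)))
        if spec.kind == "presence":
            log.append(
                LogEntry(
                    DateTime=moment,
                    Category="Error",
                    Type="Presence",
                    Cage=spec.cage,
                    Corner=spec.corner,
                    Notes="synthetic injected RFID presence failure",
                )
            )
        else:
            log.append(
                LogEntry(
                    DateTime=moment,
                    Category="Warning",
                    Type="Lickometer",
                    Cage=spec.cage,
                    Corner=spec.corner,
                    Side=spec.side,
                    Notes="synthetic injected lickometer failure",
                )
            )
        padded = TimeInterval(moment - pad, moment + pad)
        affected = []
        for visit in visits:
            if spec.kind == "presence":
                hit = (
                    visit.Cage == spec.cage
                    and visit.Corner == spec.corner
                    and visit.Start < padded.end
                    and padded.start < visit.End
                )
            else:
                hit = visit.Cage == spec.cage and any(
                    poke.Side == spec.side
                    and poke.Start < padded.end
                    and padded.start < poke.End
                    for poke in visit.Nosepokes
                )
            if hit:
                affected.append((visit.Animal.Name, visit.Start.isoformat()))
        failures.append(
            InjectedFailure(
                spec=spec,
                time=moment,
                padded_interval=padded,
                affected_visits=tuple(affected),
            )
        )

    truth = GroundTruth(
        rewarded_corner=rewarded_corner,
        rewarded_side=rewarded_side,
        cage_of=cage_of,
        phase_probabilities={
            spec.name: (spec.p_corner, spec.p_side) for spec in config.phases
        },
        failures=tuple(failures),
        total_visits=len(visits),
    )

    session_interval = TimeInterval(at_ms(0), at_ms(experiment_end_ms))
    full = SessionData(
        visits=tuple(visits),
        animals=animals,
        groups=groups,
        environment=tuple(sorted(environment, key=lambda e: e.DateTime)),
        log=tuple(sorted(log, key=lambda e: e.DateTime)),
        hardware=tuple(sorted(hardware, key=lambda e: e.DateTime)),
        session_interval=session_interval,
        source_label="session-01",
    )
    if config.n_sessions == 1:
        return [full], timeline, truth
    return _split_session(full, config.n_sessions), timeline, truth


def _resolve_collisions(drafts: List[_VisitDraft], end_ms: int) -> None:
    """Enforce one-mouse-per-corner occupancy by shifting later visits.

    A colliding visit is moved to start 1 ms after the earlier visit ends,
    keeping its duration and nosepoke offsets.  Shifts larger than one hour
    mean the configured rate is incompatible with corner exclusivity.
    """
    by_location: Dict[tuple, List[_VisitDraft]] = {}
    for draft in drafts:
        by_location.setdefault((draft.cage, draft.corner), []).append(draft)
    for located in by_location.values():
        located.sort(key=lambda d: (d.start_ms, d.mouse))
        previous_end = None
        for draft in located:
            if previous_end is not None and draft.start_ms <= previous_end:
                shift = previous_end + 1 - draft.start_ms
                if shift > 3600_000 or draft.end_ms + shift > end_ms + 3600_000:
                    raise GenerationError(
                        "visit rate too high: corner-occupancy exclusivity "
                        "cannot be satisfied without distorting the schedule"
                    )
                draft.start_ms += shift
                draft.end_ms += shift
            previous_end = draft.end_ms


def _split_session(full: SessionData, n_sessions: int) -> List[SessionData]:
    """Cut one experiment into consecutive sessions along the time axis."""
    start = full.session_interval.start
    end = full.session_interval.end
    total_ms = int((end - start) / _MS)
    # boundaries snap to the millisecond grid of the dialect
    bounds = [
        start + _MS * int(round(total_ms * k / n_sessions))
        for k in range(n_sessions + 1)
    ]
    sessions = []
    for k in range(n_sessions):
        window = TimeInterval(bounds[k], bounds[k + 1])

        def inside(moment, last=(k == n_sessions - 1)):
            return moment in window or (last and moment == window.end)

        sessions.append(
            SessionData(
                visits=tuple(v for v in full.visits if inside(v.Start)),
                animals=full.animals,
                groups=full.groups,
                environment=tuple(
                    e for e in full.environment if inside(e.DateTime)
                ),
                log=tuple(e for e in full.log if inside(e.DateTime)),
                hardware=tuple(e for e in full.hardware if inside(e.DateTime)),
                session_interval=window,
                source_label=f"session-{k + 1:02d}",
            )
        )
    return sessions


def partition_records(
    session: SessionData, n_parts: int, rng: np.random.Generator
) -> List[SessionData]:
    """Randomly scatter a session's records over ``n_parts`` sessions.

    Unlike :func:`generate_experiment`'s time-based session split, this
    assigns each record to a part uniformly at random (each part keeps the
    full roster and the original session interval).  Merging the parts must
    conserve all per-kind record counts; useful for exercising merge
    invariants.
    """
    if n_parts < 1:
        raise DomainError("n_parts must be >= 1")
    parts: List[dict] = [
        {"visits": [], "environment": [], "log": [], "hardware": []}
        for _ in range(n_parts)
    ]
    for kind in ("visits", "environment", "log", "hardware"):
        for record in getattr(session, kind):
            parts[int(rng.integers(0, n_parts))][kind].append(record)
    return [
        SessionData(
            visits=tuple(part["visits"]),
            animals=session.animals,
            groups=session.groups,
            environment=tuple(part["environment"]),
            log=tuple(part["log"]),
            hardware=tuple(part["hardware"]),
            session_interval=session.session_interval,
            source_label=f"{session.source_label}-part{k + 1}",
        )
        for k, part in enumerate(parts)
    ]
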