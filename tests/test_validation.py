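import random
from datetime import datetime, timedelta, timezone

import pytest
from hypothesis import given
from hypothesis import strategies as st

from helpers import brute_interval_union
from homecage.archive import SessionData, merge_sessions
from homecage.model import Animal, LogEntry, Nosepoke, TimeInterval, Visit
from homecage.validation import (
    check_integrity,
    detect_failures,
    detect_lickometer_warnings,
    detect_presence_errors,
    flag_affected,
    register_detector,
)

TZ = timezone(timedelta(hours=2))
T0 = datetime(2012, 8, 1, 13, 0, tzinfo=TZ)


def at(seconds):
    return T0 + timedelta(seconds=seconds)


def presence_entry(seconds, cage=1, corner=3):
    return LogEntry(DateTime=at(seconds), Category="Error", Type="Presence",
                    Cage=cage, Corner=corner)


def lick_entry(seconds, cage=1, corner=1, side=1):
    return LogEntry(DateTime=at(seconds), Category="Warning",
                    Type="Lickometer", Cage=cage, Corner=corner, Side=side)


def test_no_matching_entries_yield_no_periods():
    noise = [LogEntry(DateTime=at(0), Category="Info", Type="Application")]
    assert detect_presence_errors(noise) == []
    assert detect_lickometer_warnings(noise) == []


def test_single_entry_yields_symmetric_padded_period():
    periods = detect_presence_errors([presence_entry(7200)], pad=3600)
    assert len(periods) == 1
    period = periods[0]
    assert period.interval == TimeInterval(at(3600), at(10800))
    assert (period.cage, period.corner, period.side) == (1, 3, None)
    assert period.kind == "PresenceError"
    assert len(period.source_entries) == 1


def test_lickometer_period_is_scoped_to_a_side():
    periods = detect_lickometer_warnings([lick_entry(7200)], pad=600)
    assert len(periods) == 1
    assert periods[0].side == 1
    assert periods[0].interval == TimeInterval(at(6600), at(7800))


@pytest.mark.parametrize("detect, make_entry", [
    (detect_presence_errors, presence_entry),
    (detect_lickometer_warnings, lick_entry),
])
def test_nearby_entries_coalesce_like_brute_force_union(detect, make_entry):
    offsets = [0, 1800, 9000, 9300, 30000]
    periods = detect([make_entry(s) for s in offsets], pad=3600)
    expected = brute_interval_union(
        [(at(s - 3600), at(s + 3600)) for s in offsets]
    )
    assert [(p.interval.start, p.interval.end) for p in periods] == expected
    # the 1800 s window's end touches the 9000 s window's start: adjacent
    # half-open windows coalesce, so the first four entries share one period
    assert len(periods) == 2
    assert len(periods[0].source_entries) == 4


def test_different_corners_never_coalesce():
    entries = [presence_entry(0, corner=1), presence_entry(60, corner=2)]
    periods = detect_presence_errors(entries, pad=3600)
    assert len(periods) == 2


def test_coalescing_is_order_independent_and_idempotent():
    entries = [presence_entry(s) for s in (9000, 0, 1800, 9300)]
    reference = detect_presence_errors(entries, pad=3600)
    shuffled = entries[:]
    random.Random(4).shuffle(shuffled)
    assert detect_presence_errors(shuffled, pad=3600) == reference


def make_visit(animal, start, end, cage=1, corner=3, pokes=()):
    return Visit(Start=at(start), End=at(end), Cage=cage, Corner=corner,
                 Animal=animal, Nosepokes=tuple(pokes))


def test_flagging_respects_cage_and_corner_scope():
    jerry = Animal(Name="Jerry", Tag="t1")
    inside = make_visit(jerry, 7000, 7100)                     # overlaps
    other_cage = make_visit(jerry, 7000, 7100, cage=2)         # same time
    other_corner = make_visit(jerry, 7000, 7100, corner=1)
    before = make_visit(jerry, 0, 100)
    periods = detect_presence_errors([presence_entry(7200)], pad=3600)
    flags = flag_affected([inside, other_cage, other_corner, before], periods)
    assert flags[inside] == {periods[0]}
    assert flags[other_cage] == set()
    assert flags[other_corner] == set()
    assert flags[before] == set()


def test_lickometer_flagging_requires_a_matching_poke():
    jerry = Animal(Name="Jerry", Tag="t1")
    hit = make_visit(jerry, 7000, 7100, corner=1, pokes=[
        Nosepoke(Start=at(7010), End=at(7020), Side=1),
    ])
    wrong_side = make_visit(jerry, 7000, 7100, corner=1, pokes=[
        Nosepoke(Start=at(7010), End=at(7020), Side=2),
    ])
    no_pokes = make_visit(jerry, 7000, 7100, corner=1)
    periods = detect_lickometer_warnings([lick_entry(7200)], pad=3600)
    flags = flag_affected([hit, wrong_side, no_pokes], periods)
    assert flags[hit] == {periods[0]}
    assert flags[wrong_side] == set()
    assert flags[no_pokes] == set()


def test_generator_injected_failures_match_ground_truth(failure_experiment):
    sessions, _, truth = failure_experiment
    data = merge_sessions(sessions)
    presence = detect_presence_errors(data.log)
    lickometer = detect_lickometer_warnings(data.log)
    assert len(presence) == 1 and len(lickometer) == 1
    assert presence[0].interval == truth.failures[0].padded_interval
    assert lickometer[0].interval == truth.failures[1].padded_interval

    flags = flag_affected(data.visits, presence + lickometer)
    for period, failure in zip(presence + lickometer, truth.failures):
        flagged = {
            (v.Animal.Name, v.Start.isoformat())
            for v, hits in flags.items()
            if period in hits
        }
        assert flagged == set(failure.affected_visits)


@given(st.integers(min_value=0, max_value=7200))
def test_detection_is_monotone_in_pad(pad):
    entries = [presence_entry(7200), presence_entry(20000)]
    jerry = Animal(Name="Jerry", Tag="t1")
    visits = [make_visit(jerry, s, s + 50) for s in range(0, 30000, 700)]
    narrow = flag_affected(visits, detect_presence_errors(entries, pad=pad))
    wide = flag_affected(
        visits, detect_presence_errors(entries, pad=pad + 900)
    )
    for visit in visits:
        if narrow[visit]:
            assert wide[visit]


def test_custom_detector_registration():
    register_detector("TempSensorFailure", "Warning", "Temperature", ("Cage",))
    entries = [
        LogEntry(DateTime=at(100), Category="Warning", Type="Temperature",
                 Cage=2),
    ]
    periods = detect_failures(entries, "TempSensorFailure", pad=60)
    assert len(periods) == 1
    assert periods[0].cage == 2
    assert periods[0].kind == "TempSensorFailure"


def session_of(visits, animals, span=(0, 40000)):
    return SessionData(
        visits=tuple(sorted(visits, key=lambda v: v.Start)),
        animals=animals,
        groups={},
        environment=(),
        log=(),
        hardware=(),
        session_interval=TimeInterval(at(span[0]), at(span[1])),
    )


def test_clean_generated_data_has_zero_findings(small_data):
    assert check_integrity(small_data) == []


def test_each_planted_inconsistency_reported_exactly_once():
    jerry = Animal(Name="Jerry", Tag="t1")
    tom = Animal(Name="Tom", Tag="t2")
    animals = {"Jerry": jerry, "Tom": tom}
    out_of_bounds = make_visit(jerry, 100, 150, corner=1, pokes=[
        Nosepoke(Start=at(90), End=at(95), Side=1),   # before the visit
    ])
    mismatched = make_visit(jerry, 200, 250, corner=1, pokes=[
        Nosepoke(Start=at(210), End=at(215), Side=5),  # side of corner 3
    ])
    colliding_a = make_visit(jerry, 300, 400, corner=2)
    colliding_b = make_visit(tom, 350, 420, corner=2)
    stray = make_visit(tom, 50000, 50100, corner=3)    # after session end
    clean = make_visit(tom, 500, 510, corner=4, pokes=[
        Nosepoke(Start=at(501), End=at(502), Side=7),
    ])
    session = session_of(
        [out_of_bounds, mismatched, colliding_a, colliding_b, stray, clean],
        animals,
    )
    findings = check_integrity(session)
    kinds = sorted(f.kind for f in findings)
    assert kinds == [
        "nosepoke_outside_visit",
        "overlapping_visits",
        "side_corner_mismatch",
        "visit_outside_session",
    ]


def test_seventeen_mice_in_one_cage_is_a_capacity_finding():
    animals = {
        f"M{i}": Animal(Name=f"M{i}", Tag=f"tag{i}") for i in range(17)
    }
    visits = [
        make_visit(animals[f"M{i}"], 100 * i, 100 * i + 10, corner=1)
        for i in range(17)
    ]
    findings = check_integrity(session_of(visits, animals, span=(0, 10000)))
    capacity = [f for f in findings if f.kind == "cage_overcapacity"]
    assert len(capacity) == 1
    assert capacity[0].cage == 1
    assert "17" in capacity[0].message
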