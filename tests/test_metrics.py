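import math
import random
from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from helpers import (
    brute_discrimination,
    brute_first_poke_side_counts,
    brute_intervisit,
)
from homecage.archive import merge_sessions
from homecage.errors import DomainError
from homecage.metrics import (
    corner_preference_performance,
    discrimination_performance,
    first_nosepoke_side_counts,
    intervisit_intervals,
    log_histogram,
    performance_matrix,
)
from homecage.model import Animal, Nosepoke, Visit
from homecage.query import get_visits
from homecage.synth import PhaseSpec, generate_experiment

from conftest import small_config

TZ = timezone(timedelta(hours=2))
T0 = datetime(2012, 8, 1, 13, 0, tzinfo=TZ)


def at(seconds):
    return T0 + timedelta(seconds=seconds)


JERRY = Animal(Name="Jerry", Tag="t1")


def visit(start, end, corner=1, condition=0, poke_specs=()):
    pokes = [
        Nosepoke(Start=at(s), End=at(e), Side=side, SideCondition=sc)
        for s, e, side, sc in poke_specs
    ]
    return Visit(Start=at(start), End=at(end), Cage=1, Corner=corner,
                 Animal=JERRY, CornerCondition=condition, Nosepokes=tuple(pokes))


def test_first_poke_side_counts_skip_pokeless_visits():
    visits = [
        visit(0, 10, poke_specs=[(1, 2, 1, 0), (3, 4, 2, 0)]),   # first: left
        visit(20, 30, poke_specs=[(21, 22, 1, 0)]),              # left
        visit(40, 50, poke_specs=[(44, 45, 2, 0), (41, 42, 2, 0)]),  # right
        visit(60, 70, poke_specs=[(61, 62, 1, 0)]),              # left
        visit(80, 90),                                           # pokeless
    ]
    assert first_nosepoke_side_counts(visits) == {"left": 3, "right": 1}


def test_first_poke_counts_of_pokeless_visits_are_zero():
    assert first_nosepoke_side_counts([visit(0, 10), visit(20, 30)]) == {
        "left": 0, "right": 0,
    }


def test_discrimination_performance_examples():
    signs = [1, -1, 1, 1]
    visits = [
        visit(30 * i, 30 * i + 10, condition=1,
              poke_specs=[(30 * i + 1, 30 * i + 2, 1 if s > 0 else 2, s)])
        for i, s in enumerate(signs)
    ]
    assert discrimination_performance(visits) == 0.75
    # visits to wrong corners only: undefined
    wrong = [visit(0, 10, condition=-1, poke_specs=[(1, 2, 1, 1)])]
    assert discrimination_performance(wrong) is None
    assert discrimination_performance([]) is None


def test_corner_preference_examples():
    visits = [visit(10 * i, 10 * i + 5, condition=1 if i < 4 else -1)
              for i in range(10)]
    assert corner_preference_performance(visits) == 0.4
    assert corner_preference_performance([]) is None


def test_fractions_are_invariant_under_visit_reordering(small_data):
    visits = list(small_data.visits)
    shuffled = visits[:]
    random.Random(9).shuffle(shuffled)
    assert first_nosepoke_side_counts(shuffled) == first_nosepoke_side_counts(
        visits
    )
    assert discrimination_performance(shuffled) == discrimination_performance(
        visits
    )
    assert corner_preference_performance(
        shuffled
    ) == corner_preference_performance(visits)


def test_side_counts_and_discrimination_match_raw_table_recount(
    small_archive, small_data
):
    for mouse in ("Jerry", "Tom", "Spike"):
        visits = get_visits(small_data, {mouse})
        assert first_nosepoke_side_counts(visits) == (
            brute_first_poke_side_counts(small_archive, mouse)
        )
        assert discrimination_performance(visits) == brute_discrimination(
            small_archive, mouse
        )


def test_programmed_side_choice_probability_is_recovered():
    config = small_config(
        seed=17,
        phases=(PhaseSpec(name="DISC dark", duration_hours=8.0,
                          p_corner=0.9, p_side=0.8),),
        nosepoke_mean=3.0,
        visit_rate=30.0,
    )
    sessions, _, _ = generate_experiment(config)
    visits = merge_sessions(sessions).visits
    estimate = discrimination_performance(visits)
    n = sum(1 for v in visits if v.CornerCondition > 0 and v.Nosepokes)
    assert n > 400
    bound = 3 * math.sqrt(0.8 * 0.2 / n)
    assert abs(estimate - 0.8) < bound


def test_matrix_cell_equals_scalar_metric_on_the_same_slice(
    small_data, small_experiment
):
    _, timeline, _ = small_experiment
    matrix = performance_matrix(
        small_data, timeline, ["PP 1 dark"], {"Jerry"}, "discrimination"
    )
    visits = get_visits(small_data, {"Jerry"}, timeline.bounds("PP 1 dark"))
    expected = discrimination_performance(visits)
    assert matrix.values.shape == (1, 1)
    assert matrix.values.iat[0, 0] == expected
    assert matrix.counts.iat[0, 0] == sum(
        1 for v in visits if v.CornerCondition > 0 and v.Nosepokes
    )


def test_matrix_cell_without_visits_is_undefined_with_zero_count(
    small_experiment,
):
    sessions, timeline, _ = small_experiment
    config = small_config(
        seed=19,
        phases=(
            PhaseSpec(name="quiet", duration_hours=1.0, visit_rate=0.0),
            PhaseSpec(name="busy", duration_hours=1.0),
        ),
    )
    sessions, timeline, _ = generate_experiment(config)
    data = merge_sessions(sessions)
    matrix = performance_matrix(data, timeline, ["quiet", "busy"],
                                mode="corner_preference")
    assert matrix.values["quiet"].isna().all()
    assert (matrix.counts["quiet"] == 0).all()
    assert matrix.counts["busy"].sum() > 0


def test_matrix_concatenates_over_phase_lists(small_data, small_experiment):
    _, timeline, _ = small_experiment
    both = performance_matrix(small_data, timeline,
                              ["NPA 1 dark", "PP 1 dark"],
                              mode="corner_preference")
    first = performance_matrix(small_data, timeline, ["NPA 1 dark"],
                               mode="corner_preference")
    second = performance_matrix(small_data, timeline, ["PP 1 dark"],
                                mode="corner_preference")
    import pandas as pd

    pd.testing.assert_frame_equal(
        both.values, pd.concat([first.values, second.values], axis=1)
    )


def test_group_restriction_limits_matrix_rows(small_data, small_experiment):
    _, timeline, _ = small_experiment
    matrix = performance_matrix(small_data, timeline, ["PP 1 dark"],
                                subjects="C57A", mode="corner_preference")
    assert set(matrix.mice) == {"Jerry", "Tom", "Spike"}


def test_intervisit_interval_arithmetic():
    visits = [visit(0, 10), visit(25, 30), visit(100, 110)]
    gaps = intervisit_intervals(visits)
    assert gaps == {(1, 1): [15.0, 70.0]}
    start_to_start = intervisit_intervals(visits, gap="start_to_start")
    assert start_to_start == {(1, 1): [25.0, 75.0]}
    with pytest.raises(DomainError):
        intervisit_intervals(visits, gap="middle")


def test_single_visit_corner_yields_no_intervals():
    assert intervisit_intervals([visit(0, 10)]) == {(1, 1): []}
    assert intervisit_intervals([]) == {}


def test_negative_intervals_are_reported_not_dropped():
    overlapping = [visit(0, 50), visit(30, 60)]
    assert intervisit_intervals(overlapping) == {(1, 1): [-20.0]}


def test_intervisit_matches_quadratic_oracle(small_archive, small_data):
    visits = get_visits(small_data, order="Start")
    for gap in ("end_to_start", "start_to_start"):
        computed = intervisit_intervals(visits, gap=gap)
        oracle = brute_intervisit(small_archive, gap=gap)
        assert set(computed) == set(oracle)
        for key in oracle:
            assert computed[key] == pytest.approx(oracle[key])


def test_interval_totals_identity(small_data):
    gaps = intervisit_intervals(small_data.visits)
    total = sum(len(v) for v in gaps.values())
    assert total == len(small_data.visits) - len(gaps)


def test_log_histogram_decade_bins():
    histogram = log_histogram([1.0, 10.0, 100.0], bins_per_decade=1,
                              range=(1.0, 1000.0))
    assert histogram.bins == ((1.0, 10.0), (10.0, 100.0), (100.0, 1000.0))
    assert histogram.counts == (1, 1, 1)
    assert histogram.anomalies == 0


def test_log_histogram_empty_input_is_all_zero():
    histogram = log_histogram([], bins_per_decade=2, range=(1.0, 100.0))
    assert histogram.counts == (0, 0, 0, 0)


def test_log_histogram_counts_are_conserved():
    rng = np.random.default_rng(2)
    values = list(rng.lognormal(3.0, 2.0, 500)) + [-5.0, 0.0]
    histogram = log_histogram(values, bins_per_decade=4, range=(1.0, 10000.0))
    assert histogram.total + histogram.anomalies + histogram.out_of_range == len(
        values
    )
    assert histogram.anomalies == 2


def test_log_histogram_rejects_nonpositive_range():
    with pytest.raises(DomainError):
        log_histogram([1.0], bins_per_decade=1, range=(0.0, 10.0))


def test_tidy_export_round_trips_values(small_data, small_experiment):
    _, timeline, _ = small_experiment
    matrix = performance_matrix(small_data, timeline,
                                list(timeline.names), mode="corner_preference")
    tidy = matrix.to_tidy()
    assert set(tidy.columns) == {"mouse", "phase", "performance", "n"}
    assert len(tidy) == len(matrix.mice) * len(matrix.phases)
    cell = tidy[(tidy.mouse == "Jerry") & (tidy.phase == "PP 1 dark")]
    assert cell.performance.iloc[0] == matrix.values.at["Jerry", "PP 1 dark"]
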