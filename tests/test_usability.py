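"""Usability formulas: success rate, TBE, relative efficiency, error rate, SUS."""

import itertools

import numpy as np
import pytest

from footkin.usability import (
    SUS_ADJECTIVE_BANDS,
    SUSResponse,
    TaskOutcome,
    UsabilityValidationError,
    error_rate,
    relative_efficiency,
    success_rate,
    sus_adjective,
    sus_score,
    time_based_efficiency,
    usability_report,
)


def _task(user="u1", task="t1", status="full_success", time_s=10.0,
          defects=0, opportunities=5):
    return TaskOutcome(user_id=user, task_id=task, status=status,
                       time_s=time_s, defects=defects,
                       opportunities=opportunities)


def test_success_rate_worked_examples():
    assert success_rate([_task(task=f"t{i}") for i in range(30)]) == 100.0
    assert success_rate([_task(task=f"t{i}", status="partial_success")
                         for i in range(30)]) == 50.0
    mixed = ([_task(task=f"t{i}") for i in range(26)]
             + [_task(task=f"p{i}", status="partial_success") for i in range(2)]
             + [_task(task=f"f{i}", status="failure") for i in range(2)])
    assert success_rate(mixed) == pytest.approx(90.0)


def test_success_rate_empty_raises():
    with pytest.raises(UsabilityValidationError):
        success_rate([])


def test_time_based_efficiency_examples():
    two_ok = [_task(task="t1", time_s=10.0), _task(task="t2", time_s=20.0)]
    assert time_based_efficiency(two_ok) == pytest.approx(0.075)
    with_fail = [_task(task="t1", time_s=10.0),
                 _task(task="t2", time_s=20.0, status="failure")]
    assert time_based_efficiency(with_fail) == pytest.approx(0.05)
    all_fail = [_task(task="t1", status="failure"),
                _task(task="t2", status="partial_success")]
    assert time_based_efficiency(all_fail) == 0.0


def test_time_based_efficiency_duplicate_pair_raises():
    with pytest.raises(UsabilityValidationError, match="duplicate"):
        time_based_efficiency([_task(), _task(time_s=5.0)])


def test_tbe_monotone_in_task_time(rng):
    tasks = [_task(task=f"t{i}", time_s=float(t))
             for i, t in enumerate(rng.uniform(5, 50, 10))]
    base = time_based_efficiency(tasks)
    slower = list(tasks)
    slower[3] = _task(task="t3", time_s=tasks[3].time_s * 2)
    assert time_based_efficiency(slower) <= base


def test_relative_efficiency_truncation_reproduces_printed_ratio():
    # 0.05348 / 0.0442 = 1.20995...: truncation gives 1.209, rounding 1.210
    assert relative_efficiency(0.0442, 0.05348) == 1.209
    assert relative_efficiency(0.0442, 0.05348, mode="round") == 1.210
    assert relative_efficiency(0.05, 0.05) == 1.000
    assert relative_efficiency(0.05, 0.10) == 2.000
    with pytest.raises(UsabilityValidationError):
        relative_efficiency(0.0, 0.1)


def test_error_rate_examples_and_monotonicity():
    tasks = [_task(task=f"t{i}", defects=1 if i < 3 else 0, opportunities=15)
             for i in range(10)]
    assert error_rate(tasks) == pytest.approx(3 / 150) == pytest.approx(0.02)
    assert error_rate([_task()]) == 0.0
    assert error_rate([_task(defects=5, opportunities=5)]) == 1.0
    more = tasks[:-1] + [_task(task="t9", defects=1, opportunities=15)]
    assert error_rate(more) >= error_rate(tasks)


def test_task_outcome_validation():
    with pytest.raises(UsabilityValidationError):
        _task(status="done")
    with pytest.raises(UsabilityValidationError):
        _task(time_s=0.0)
    with pytest.raises(UsabilityValidationError):
        _task(defects=6, opportunities=5)


def test_sus_score_extremes_and_midpoint():
    assert sus_score(SUSResponse((3,) * 10)) == 50.0
    assert sus_score(SUSResponse((5, 1) * 5)) == 100.0
    assert sus_score(SUSResponse((1, 5) * 5)) == 0.0
    with pytest.raises(UsabilityValidationError):
        SUSResponse((0, 3, 3, 3, 3, 3, 3, 3, 3, 3))
    with pytest.raises(UsabilityValidationError):
        SUSResponse((3,) * 9)


def test_sus_scores_are_multiples_of_2_5(rng):
    for _ in range(10_000):
        items = tuple(int(v) for v in rng.integers(1, 6, 10))
        score = sus_score(SUSResponse(items))
        assert 0.0 <= score <= 100.0
        assert score % 2.5 == 0.0


def test_sus_adjective_bands():
    assert sus_adjective(66.5) == "Good"
    assert sus_adjective(100.0) == "Best Imaginable"
    assert sus_adjective(10.0) == "Worst Imaginable"
    assert sus_adjective(25.0) == "Worst Imaginable"
    assert sus_adjective(25.05) == "Worst Imaginable"   # printed gap -> lower band
    assert sus_adjective(51.65) == "Poor"               # printed gap -> lower band
    assert sus_adjective(84.05) == "Excellent"
    with pytest.raises(UsabilityValidationError):
        sus_adjective(101.0)


def test_band_bounds_cover_every_achievable_score():
    achievable = {2.5 * k for k in range(41)}
    for score in sorted(achievable):
        name = sus_adjective(score)
        assert name in {b[2] for b in SUS_ADJECTIVE_BANDS}


def test_usability_report_flags_and_scales():
    tasks = [_task(task=f"t{i}", time_s=12.0) for i in range(10)]
    responses = [SUSResponse((4, 2, 4, 2, 4, 2, 4, 2, 4, 2))]
    report = usability_report(tasks, responses, expert_tbe=0.09)
    assert report["success_rate_pct"] == 100.0
    assert report["flags"]["success_acceptable"]
    assert report["error_rate_pct"] == 100.0 * report["error_rate_proportion"]
    assert report["sus_mean"] == 75.0
    assert report["sus_adjective"] == "Excellent"
    # truncation of 0.09 / (1/12) = 1.0799999... floors to 1.079
    assert report["relative_efficiency"] == 1.079
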