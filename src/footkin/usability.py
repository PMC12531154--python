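"""Usability metrics: task success rate, time-based efficiency, error rate,
and System Usability Scale (SUS) scoring with adjective-band interpretation.

Formulas
--------
* success rate = 100 * (S + 0.5 * PS) / TotalTasks, where S counts full and
  PS partial successes; >= 78% is conventionally acceptable.
* time-based efficiency (TBE) = (sum_ij n_ij / t_ij) / (N * R) in tasks per
  second, with n_ij = 1 only for a full success (partials count 0 here; they
  only weigh into the success rate), N distinct tasks, R distinct users.
* relative efficiency = expert TBE / user TBE; values near 1 mean a novice
  is about as fast as an expert. Reported truncated to 3 decimals by
  default (rounding is available via ``mode="round"``); full precision is
  retained internally.
* error rate = total defects / total opportunities; <= 0.02 is the
  conventional benchmark. Reported on both the proportion and the percent
  scale to avoid unit ambiguity.
* SUS: ten 1-5 Likert items; score = 2.5 * (sum over odd items (v - 1) +
  sum over even items (5 - v)), always a multiple of 2.5 in [0, 100]
  (standard Brooke scoring).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

STATUSES = ("full_success", "partial_success", "failure")

#: Adjective bands as printed on the Sauro rating scale: (low, high, name).
#: Scores in a gap between printed intervals resolve to the band below.
SUS_ADJECTIVE_BANDS: Tuple[Tuple[float, float, str], ...] = (
    (0.0, 25.0, "Worst Imaginable"),
    (25.1, 51.6, "Poor"),
    (51.7, 62.6, "OK"),
    (62.7, 72.5, "Good"),
    (72.6, 84.0, "Excellent"),
    (84.1, 100.0, "Best Imaginable"),
)

SUCCESS_RATE_BENCHMARK = 78.0     # percent
ERROR_RATE_BENCHMARK = 0.02       # proportion


class UsabilityValidationError(ValueError):
    """Malformed usability inputs."""


@dataclass(frozen=True)
class TaskOutcome:
    """One observed (user, task) attempt."""

    user_id: str
    task_id: str
    status: str
    time_s: float
    defects: int = 0
    opportunities: int = 1

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise UsabilityValidationError(
                f"status must be one of {STATUSES}, got {self.status!r}")
        if not (math.isfinite(self.time_s) and self.time_s > 0):
            raise UsabilityValidationError("time_s must be finite and positive")
        if self.defects < 0 or self.opportunities < 1:
            raise UsabilityValidationError(
                "defects must be >= 0 and opportunities >= 1")
        if self.defects > self.opportunities:
            raise UsabilityValidationError("defects cannot exceed opportunities")


@dataclass(frozen=True)
class SUSResponse:
    """Ten Likert items, 1 (strongly disagree) .. 5 (strongly agree)."""

    items: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.items) != 10:
            raise UsabilityValidationError(
                f"SUS needs exactly 10 items, got {len(self.items)}")
        if any(not (1 <= int(v) <= 5) or int(v) != v for v in self.items):
            raise UsabilityValidationError("each SUS item must be an integer in 1..5")


def _require_nonempty(outcomes: Sequence[TaskOutcome]) -> None:
    if not outcomes:
        raise UsabilityValidationError("empty task-outcome collection")


def success_rate(outcomes: Sequence[TaskOutcome]) -> float:
    """Percent of tasks completed, counting partial successes at half weight."""
    _require_nonempty(outcomes)
    s = sum(o.status == "full_success" for o in outcomes)
    ps = sum(o.status == "partial_success" for o in outcomes)
    return 100.0 * (s + 0.5 * ps) / len(outcomes)


def success_rate_per_user(outcomes: Sequence[TaskOutcome]) -> float:
    """Mean of per-user success rates (alternative aggregation)."""
    _require_nonempty(outcomes)
    users: Dict[str, List[TaskOutcome]] = {}
    for o in outcomes:
        users.setdefault(o.user_id, []).append(o)
    return sum(success_rate(rows) for rows in users.values()) / len(users)


def time_based_efficiency(outcomes: Sequence[TaskOutcome]) -> float:
    """Mean successful-task throughput, tasks per second.

    Requires one outcome per (user, task) pair; failed and partially
    successful tasks contribute zero to the numerator but still occupy a
    cell of the N x R denominator.
    """
    _require_nonempty(outcomes)
    seen = set()
    for o in outcomes:
        key = (o.user_id, o.task_id)
        if key in seen:
            raise UsabilityValidationError(f"duplicate (user, task) pair {key}")
        seen.add(key)
    n_tasks = len({o.task_id for o in outcomes})
    n_users = len({o.user_id for o in outcomes})
    numerator = sum(1.0 / o.time_s for o in outcomes if o.status == "full_success")
    return numerator / (n_tasks * n_users)


def relative_efficiency(user_tbe: float, expert_tbe: float,
                        mode: str = "truncate") -> float:
    """Expert-to-user TBE ratio, reported at 3 decimals.

    ``mode="truncate"`` (default) truncates toward zero; ``"round"`` uses
    round-half-even; ``"exact"`` returns full precision.
    """
    if user_tbe <= 0 or expert_tbe <= 0:
        raise UsabilityValidationError("TBE values must be positive")
    ratio = expert_tbe / user_tbe
    if mode == "truncate":
        return math.floor(ratio * 1000.0) / 1000.0
    if mode == "round":
        return round(ratio, 3)
    if mode == "exact":
        return ratio
    raise ValueError(f"unknown mode {mode!r}")


def error_rate(outcomes: Sequence[TaskOutcome]) -> float:
    """Total defects over total opportunities (proportion in [0, 1])."""
    _require_nonempty(outcomes)
    opportunities = sum(o.opportunities for o in outcomes)
    if opportunities <= 0:
        raise UsabilityValidationError("total opportunities must be positive")
    return sum(o.defects for o in outcomes) / opportunities


def sus_score(response: SUSResponse) -> float:
    """Standard SUS score in [0, 100], a multiple of 2.5."""
    odd = sum(response.items[i] - 1 for i in range(0, 10, 2))
    even = sum(5 - response.items[i] for i in range(1, 10, 2))
    return 2.5 * (odd + even)


def sus_adjective(score: float,
                  bands: Sequence[Tuple[float, float, str]] = SUS_ADJECTIVE_BANDS
                  ) -> str:
    """Adjective band for a SUS score; printed gaps resolve downward."""
    if not 0.0 <= score <= 100.0:
        raise UsabilityValidationError(f"SUS score {score} outside [0, 100]")
    below = bands[0][2]
    for lo, hi, name in bands:
        if lo <= score <= hi:
            return name
        if score < lo:
            return below        # score fell in the printed gap below this band
        below = name
    return bands[-1][2]


def usability_report(outcomes: Sequence[TaskOutcome],
                     responses: Sequence[SUSResponse] = (),
                     expert_tbe: float | None = None) -> Dict:
    """Aggregate metrics with benchmark flags, on explicit scales."""
    tbe = time_based_efficiency(outcomes)
    err = error_rate(outcomes)
    report: Dict = {
        "success_rate_pct": success_rate(outcomes),
        "success_rate_per_user_pct": success_rate_per_user(outcomes),
        "time_based_efficiency_tasks_per_s": tbe,
        "error_rate_proportion": err,
        "error_rate_pct": 100.0 * err,
        "flags": {
            "success_acceptable": success_rate(outcomes) >= SUCCESS_RATE_BENCHMARK,
            "error_rate_reasonable": err <= ERROR_RATE_BENCHMARK,
        },
    }
    if expert_tbe is not None and tbe > 0:
        rel = relative_efficiency(tbe, expert_tbe)
        report["relative_efficiency"] = rel
        report["flags"]["efficiency_normal"] = 0.8 <= rel <= 1.25
    if responses:
        scores = [sus_score(r) for r in responses]
        mean = sum(scores) / len(scores)
        report["sus_scores"] = scores
        report["sus_mean"] = mean
        report["sus_adjective"] = sus_adjective(mean)
    return report
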