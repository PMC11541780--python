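"""Behavioral performance summaries and participant inclusion screening.

Six inclusion criteria are applied: (1) complete data for both runs of
both tasks; (2) primarily right-handed (at least 3 of 5 handedness items
with the right hand); (3) mainstream-dialect status; (4) nonverbal IQ and
core language standardized scores above 70; (5) acceptable in-scanner
performance — accuracy strictly above 50% on the perceptual control and
the easy (SCon, PVio) conditions in every run — with no response bias,
i.e. a yes/no accuracy difference of at most 40 percentage points
(|SCon - InCon| and |Gram - PVio|); (6) acceptable head motion in every
run (delegated to the motion screen).

Non-response trials count as incorrect.  Mean reaction times are computed
over correctly answered trials only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behavior import BehavioralRecord
from .design import GRAMMATICALITY, PLAUSIBILITY, TaskDesign

ACCURACY_FLOOR_PCT = 50.0
BIAS_LIMIT_PCT = 40.0
SCORE_FLOOR = 70.0
HANDEDNESS_MIN_RIGHT_ITEMS = 3

CRITERIA = ("completeness", "handedness", "dialect", "iq_language", "performance", "bias", "motion")

#: conditions whose accuracy must exceed the floor, per task
EASY_CONDITIONS = {GRAMMATICALITY: ("PC", "PVio"), PLAUSIBILITY: ("PC", "SCon")}
#: (yes-condition, no-condition) pairs for the response-bias check
BIAS_PAIRS = {GRAMMATICALITY: ("Gram", "PVio"), PLAUSIBILITY: ("SCon", "InCon")}


@dataclass
class PerformanceSummary:
    """Per-condition accuracy (%) and mean RT (ms, correct trials only)."""

    task_id: str
    run_id: int
    accuracy: dict[str, float]
    mean_rt: dict[str, float | None]
    n_trials: dict[str, int]


@dataclass
class InclusionDecision:
    included: bool
    failed_criteria: list[str]

    def __post_init__(self) -> None:
        if self.included != (not self.failed_criteria):
            raise ValueError("included must be equivalent to an empty failure list")


def compute_performance(records: list[BehavioralRecord], design: TaskDesign) -> PerformanceSummary:
    """Accuracy and correct-trial mean RT per condition for one run."""
    if len(records) != len(design.trials):
        raise ValueError(
            f"{len(records)} records do not align with {len(design.trials)} design trials"
        )
    accuracy: dict[str, float] = {}
    mean_rt: dict[str, float | None] = {}
    n_trials: dict[str, int] = {}
    for cond in design.conditions:
        recs = [r for r, t in zip(records, design.trials) if t.condition == cond]
        if not recs:
            raise ValueError(f"no trials for condition {cond!r}")
        n_trials[cond] = len(recs)
        n_correct = sum(r.correct for r in recs)
        accuracy[cond] = 100.0 * n_correct / len(recs)
        correct_rts = [r.rt for r in recs if r.correct and r.rt is not None]
        mean_rt[cond] = float(np.mean(correct_rts)) if correct_rts else None
    return PerformanceSummary(
        task_id=design.task_id, run_id=design.run_id,
        accuracy=accuracy, mean_rt=mean_rt, n_trials=n_trials,
    )


def apply_inclusion(
    performance: dict[str, list[PerformanceSummary]],
    handedness_right_items: int | None = None,
    dialect_ok: bool | None = None,
    nonverbal_score: float | None = None,
    language_score: float | None = None,
    motion_ok_by_run: list[bool] | None = None,
    complete: bool = True,
    accuracy_floor: float = ACCURACY_FLOOR_PCT,
    bias_limit: float = BIAS_LIMIT_PCT,
) -> InclusionDecision:
    """Apply the six inclusion criteria; every failed criterion is reported.

    ``performance`` maps task id to its per-run summaries.  The
    performance and bias criteria are evaluated per run and fail if any
    run fails.
    """
    missing = [
        name
        for name, value in [
            ("handedness_right_items", handedness_right_items),
            ("dialect_ok", dialect_ok),
            ("nonverbal_score", nonverbal_score),
            ("language_score", language_score),
            ("motion_ok_by_run", motion_ok_by_run),
        ]
        if value is None
    ]
    if missing:
        raise ValueError(f"missing assessment fields: {missing}")

    failed: list[str] = []
    have_both = all(task in performance and performance[task] for task in (GRAMMATICALITY, PLAUSIBILITY))
    if not (complete and have_both):
        failed.append("completeness")
    if handedness_right_items < HANDEDNESS_MIN_RIGHT_ITEMS:
        failed.append("handedness")
    if not dialect_ok:
        failed.append("dialect")
    if nonverbal_score <= SCORE_FLOOR or language_score <= SCORE_FLOOR:
        failed.append("iq_language")

    perf_fail = bias_fail = False
    for task, summaries in performance.items():
        for summ in summaries:
            for cond in EASY_CONDITIONS.get(task, ()):
                if cond in summ.accuracy and summ.accuracy[cond] <= accuracy_floor:
                    perf_fail = True
            yes_cond, no_cond = BIAS_PAIRS.get(task, (None, None))
            if yes_cond in summ.accuracy and no_cond in summ.accuracy:
                if abs(summ.accuracy[yes_cond] - summ.accuracy[no_cond]) > bias_limit:
                    bias_fail = True
    if perf_fail:
        failed.append("performance")
    if bias_fail:
        failed.append("bias")
    if not all(motion_ok_by_run):
        failed.append("motion")

    return InclusionDecision(included=not failed, failed_criteria=failed)
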