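"""Trial-level task designs for the two auditory sentence-judgment tasks.

Each participant performs two tasks in the scanner: a grammaticality
judgment ("does the way she speaks sound right?") with conditions
Gram / FVio / PVio / PC, and a plausibility judgment ("does the way she
speaks make sense?") with conditions SCon / WCon / InCon / PC.  PC is a
frequency-modulated noise perceptual control shared by both tasks.  A trial
is an auditory sentence (2.7-4.5 s), a 2.3 s response window, and an
inter-trial interval drawn in equal proportions from {0, 575, 1150} ms, so
trial length ranges from 5000 to 7950 ms.  Condition order is
pseudo-randomized so that no more than five consecutive trials share the
same expected yes/no response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GRAMMATICALITY = "grammaticality"
PLAUSIBILITY = "plausibility"

TASK_CONDITIONS: dict[str, tuple[str, ...]] = {
    GRAMMATICALITY: ("Gram", "FVio", "PVio", "PC"),
    PLAUSIBILITY: ("SCon", "WCon", "InCon", "PC"),
}

#: Correct button per condition ("yes" = right index, "no" = right middle).
EXPECTED_RESPONSE: dict[str, str] = {
    "Gram": "yes",
    "FVio": "no",
    "PVio": "no",
    "SCon": "yes",
    "WCon": "yes",
    "InCon": "no",
    "PC": "yes",
}

MAX_CONSECUTIVE_SAME_RESPONSE = 5

DEFAULT_SENTENCE_DURATION_RANGE = (2.7, 4.5)
DEFAULT_RESPONSE_WINDOW = 2.3
DEFAULT_ITI_MENU = (0.0, 0.575, 1.150)
DEFAULT_REPETITION_TIME = 2.0
#: Trailing rest appended to each run so the hemodynamic response can
#: return to baseline before the run ends.
RUN_TAIL_SECONDS = 10.0


class DesignConstraintError(RuntimeError):
    """Raised when a design constraint cannot be satisfied."""


@dataclass(frozen=True)
class Trial:
    condition: str
    onset: float
    sentence_duration: float
    response_window: float
    iti: float
    expected_response: str

    @property
    def total_duration(self) -> float:
        return self.sentence_duration + self.response_window + self.iti


@dataclass
class TaskDesign:
    """One run of one task: ordered trials plus the acquisition TR."""

    task_id: str
    run_id: int
    trials: list[Trial]
    repetition_time: float = DEFAULT_REPETITION_TIME

    @property
    def conditions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.trials:
            seen.setdefault(t.condition, None)
        return tuple(seen)

    @property
    def duration(self) -> float:
        """Run length: last trial offset plus trailing rest."""
        last = self.trials[-1]
        return last.onset + last.total_duration + RUN_TAIL_SECONDS

    @property
    def n_volumes(self) -> int:
        return math.ceil(self.duration / self.repetition_time)

    def validate(self) -> None:
        if self.task_id in TASK_CONDITIONS:
            allowed = set(TASK_CONDITIONS[self.task_id])
            bad = {t.condition for t in self.trials} - allowed
            if bad:
                raise ValueError(f"conditions {sorted(bad)} not in task {self.task_id!r}")
        onsets = [t.onset for t in self.trials]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("trial onsets must be strictly increasing")
        run = 1
        for a, b in zip(self.trials, self.trials[1:]):
            run = run + 1 if a.expected_response == b.expected_response else 1
            if run > MAX_CONSECUTIVE_SAME_RESPONSE:
                raise ValueError(
                    f"more than {MAX_CONSECUTIVE_SAME_RESPONSE} consecutive "
                    "trials share the same expected response"
                )

    def to_events_frame(self) -> pd.DataFrame:
        """BIDS-style events table (onset, duration, trial_type, ...)."""
        return pd.DataFrame(
            {
                "onset": [t.onset for t in self.trials],
                "duration": [t.sentence_duration for t in self.trials],
                "trial_type": [t.condition for t in self.trials],
                "response_window": [t.response_window for t in self.trials],
                "iti": [t.iti for t in self.trials],
                "expected_response": [t.expected_response for t in self.trials],
            }
        )

    @classmethod
    def from_events_frame(
        cls,
        frame: pd.DataFrame,
        task_id: str,
        run_id: int,
        repetition_time: float = DEFAULT_REPETITION_TIME,
    ) -> "TaskDesign":
        trials = [
            Trial(
                condition=str(r.trial_type),
                onset=float(r.onset),
                sentence_duration=float(r.duration),
                response_window=float(r.response_window),
                iti=float(r.iti),
                expected_response=str(r.expected_response),
            )
            for r in frame.itertuples()
        ]
        return cls(task_id=task_id, run_id=run_id, trials=trials, repetition_time=repetition_time)


def trial_duration_bounds(
    sentence_duration_range: tuple[float, float] = DEFAULT_SENTENCE_DURATION_RANGE,
    response_window: float = DEFAULT_RESPONSE_WINDOW,
    iti_menu: tuple[float, ...] = DEFAULT_ITI_MENU,
) -> tuple[float, float]:
    """Attainable (min, max) total trial duration in seconds."""
    lo, hi = sentence_duration_range
    return lo + response_window + min(iti_menu), hi + response_window + max(iti_menu)


def _balanced_draw(menu: tuple[float, ...], n: int, rng: np.random.Generator) -> np.ndarray:
    """n draws from menu with counts as equal as integer division allows."""
    reps, rem = divmod(n, len(menu))
    pool = list(menu) * reps + list(rng.choice(menu, size=rem, replace=False)) if rem else list(menu) * reps
    pool = np.asarray(pool, dtype=float)
    rng.shuffle(pool)
    return pool


def _order_with_response_constraint(
    conditions: list[str],
    expected: dict[str, str],
    rng: np.random.Generator,
    max_retries: int,
) -> list[str]:
    arr = np.asarray(conditions, dtype=object)
    for _ in range(max_retries):
        perm = rng.permutation(arr)
        run, ok = 1, True
        for a, b in zip(perm, perm[1:]):
            run = run + 1 if expected[a] == expected[b] else 1
            if run > MAX_CONSECUTIVE_SAME_RESPONSE:
                ok = False
                break
        if ok:
            return list(perm)
    raise DesignConstraintError(
        f"could not order trials with no more than {MAX_CONSECUTIVE_SAME_RESPONSE} "
        f"consecutive identical expected responses after {max_retries} attempts"
    )


def build_task_design(
    task_id: str,
    n_runs: int = 2,
    trials_per_condition: int = 20,
    sentence_duration_range: tuple[float, float] = DEFAULT_SENTENCE_DURATION_RANGE,
    response_window: float = DEFAULT_RESPONSE_WINDOW,
    iti_menu: tuple[float, ...] = DEFAULT_ITI_MENU,
    repetition_time: float = DEFAULT_REPETITION_TIME,
    seed: int | np.random.SeedSequence | None = None,
    conditions: tuple[str, ...] | None = None,
    expected_response: dict[str, str] | None = None,
    max_retries: int = 10_000,
) -> list[TaskDesign]:
    """Build pseudo-randomized run designs for one task.

    Defaults give 20 trials per condition across two runs (80 trials, 40
    per run, 10 per condition per run).  ITIs are drawn in equal
    proportions from ``iti_menu``; order satisfies the consecutive-response
    constraint via rejection sampling.  Deterministic given ``seed``.
    """
    if conditions is None:
        try:
            conditions = TASK_CONDITIONS[task_id]
        except KeyError:
            raise ValueError(f"unknown task {task_id!r}; supply conditions=") from None
    expected = dict(EXPECTED_RESPONSE if expected_response is None else expected_response)
    if not iti_menu:
        raise ValueError("iti_menu must be non-empty")
    if trials_per_condition % n_runs:
        raise ValueError(
            f"trials_per_condition={trials_per_condition} not divisible by n_runs={n_runs}"
        )
    per_run = trials_per_condition // n_runs
    rng = np.random.default_rng(seed)

    designs = []
    for run_id in range(1, n_runs + 1):
        labels = [c for c in conditions for _ in range(per_run)]
        order = _order_with_response_constraint(labels, expected, rng, max_retries)
        n = len(order)
        durations = rng.uniform(*sentence_duration_range, size=n)
        itis = _balanced_draw(tuple(iti_menu), n, rng)
        trials, onset = [], 0.0
        for cond, dur, iti in zip(order, durations, itis):
            trials.append(
                Trial(
                    condition=cond,
                    onset=onset,
                    sentence_duration=float(dur),
                    response_window=response_window,
                    iti=float(iti),
                    expected_response=expected[cond],
                )
            )
            onset += trials[-1].total_duration
        d = TaskDesign(task_id=task_id, run_id=run_id, trials=trials, repetition_time=repetition_time)
        d.validate()
        designs.append(d)
    return designs
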