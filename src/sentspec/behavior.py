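"""Simulated in-scanner button responses and reaction times.

Correctness is Bernoulli per trial with a per-condition accuracy; an
incorrect trial presses the wrong button (or, with a configurable rate,
gives no response at all).  Reaction times are sampled only for trials on
which a response was given, truncated to the trial's response period.
Default accuracy and RT parameters emulate the observed performance
profile of 9-10-year-olds on these tasks (e.g. FVio accuracy 72.7%, PC
near ceiling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import TaskDesign

#: Mean accuracy (proportion correct) per condition; group means from the
#: modeled cohort's performance table.
DEFAULT_ACCURACY: dict[str, float] = {
    "Gram": 0.875,
    "FVio": 0.727,
    "PVio": 0.902,
    "SCon": 0.908,
    "WCon": 0.828,
    "InCon": 0.914,
    "PC": 0.975,  # PC is near ceiling in both tasks (96.5 / 98.4)
}

#: (mean, sd) reaction time in milliseconds per condition, correct trials.
DEFAULT_RT_MS: dict[str, tuple[float, float]] = {
    "Gram": (2217.0, 178.0),
    "FVio": (3639.0, 276.0),
    "PVio": (2193.0, 180.0),
    "SCon": (1738.0, 223.0),
    "WCon": (1872.0, 213.0),
    "InCon": (1843.0, 197.0),
    "PC": (1550.0, 900.0),
}

_OTHER = {"yes": "no", "no": "yes"}


@dataclass(frozen=True)
class BehavioralRecord:
    """Response to one trial: button pressed, RT (ms), correctness."""

    condition: str
    response: str  # "yes" | "no" | "none"
    rt: float | None
    correct: bool

    def __post_init__(self) -> None:
        if (self.rt is None) != (self.response == "none"):
            raise ValueError("rt must be present iff a response was given")


def simulate_behavior(
    design: TaskDesign,
    accuracy_by_condition: dict[str, float] | None = None,
    rt_distribution: dict[str, tuple[float, float]] | None = None,
    no_response_rate: float = 0.0,
    seed: int | np.random.SeedSequence | None = None,
) -> list[BehavioralRecord]:
    """Simulate one run's responses; deterministic given ``seed``."""
    acc = dict(DEFAULT_ACCURACY if accuracy_by_condition is None else accuracy_by_condition)
    rts = dict(DEFAULT_RT_MS if rt_distribution is None else rt_distribution)
    for cond, a in acc.items():
        if not 0.0 <= a <= 1.0:
            raise ValueError(f"accuracy for {cond} must lie in [0, 1], got {a}")
    rng = np.random.default_rng(seed)

    records = []
    for trial in design.trials:
        correct = bool(rng.random() < acc[trial.condition])
        if not correct and rng.random() < no_response_rate:
            records.append(BehavioralRecord(trial.condition, "none", None, False))
            continue
        response = trial.expected_response if correct else _OTHER[trial.expected_response]
        mean, sd = rts[trial.condition]
        # responses can arrive any time during sentence + response window
        upper = (trial.sentence_duration + trial.response_window) * 1000.0
        rt = float(np.clip(rng.normal(mean, sd), 150.0, upper))
        records.append(BehavioralRecord(trial.condition, response, rt, correct))
    return records
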