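"""Variance-component forward model for multi-voxel activation patterns.

The split-run correlation analysis downstream assumes that a voxel
pattern measured for one task in one run decomposes as

    pattern(task, run) = shared + task_specific(task) + run_noise(run)

where ``shared`` is a participant-stable spatial pattern common to both
tasks, ``task_specific`` is stable within a task across runs, and
``run_noise`` is independent per run.  With per-voxel components i.i.d.
normal with variances s2 (shared), t2 (task), r2 (run), the expected
Pearson correlations over voxels are

    within-task  r = (s2 + t2) / (s2 + t2 + r2)
    across-task  r = s2 / sqrt((s2 + t2_A + r2) (s2 + t2_B + r2))

so task-specific variance is exactly what separates within-task pattern
stability from across-task pattern sharing — the signature the group
analysis classifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import GRAMMATICALITY, PLAUSIBILITY

#: Conditions whose contrast maps feed the correlation analysis, by task.
ANALYSIS_CONDITIONS: dict[str, tuple[str, ...]] = {
    GRAMMATICALITY: ("Gram", "FVio"),
    PLAUSIBILITY: ("SCon", "InCon"),
}


@dataclass(frozen=True)
class RoiGroundTruth:
    """Generative variance components for one region."""

    sigma_shared2: float
    sigma_task2: dict[str, float]
    sigma_run2: float
    n_voxels: int

    def __post_init__(self) -> None:
        if self.sigma_shared2 < 0 or self.sigma_run2 < 0 or any(v < 0 for v in self.sigma_task2.values()):
            raise ValueError("variance components must be non-negative")
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    rois: dict[str, RoiGroundTruth]
    #: mean activation amplitude per condition (arbitrary units), used by
    #: the BOLD forward model and as a pattern offset.
    condition_amplitudes: dict[str, float] = field(default_factory=dict)


def expected_within_task_r(gt: RoiGroundTruth, task: str) -> float:
    s2, t2, r2 = gt.sigma_shared2, gt.sigma_task2[task], gt.sigma_run2
    tot = s2 + t2 + r2
    return (s2 + t2) / tot if tot > 0 else 1.0


def expected_across_task_r(gt: RoiGroundTruth, task_a: str = GRAMMATICALITY, task_b: str = PLAUSIBILITY) -> float:
    s2, r2 = gt.sigma_shared2, gt.sigma_run2
    va = s2 + gt.sigma_task2[task_a] + r2
    vb = s2 + gt.sigma_task2[task_b] + r2
    if va == 0 or vb == 0:
        return 1.0 if s2 > 0 else 0.0
    return s2 / np.sqrt(va * vb)


PatternSet = dict[str, dict[str, dict[tuple[str, int, str], np.ndarray]]]


def simulate_patterns(
    ground_truth: GroundTruth,
    n_participants: int,
    n_runs: int = 2,
    seed: int | np.random.SeedSequence | None = None,
) -> PatternSet:
    """Simulate patterns for every participant, region, task, run, condition.

    Returns ``patterns[participant][roi][(task, run, condition)]`` as a
    voxel vector.  Within a participant and region, the shared component
    is drawn once, the task component once per task, and run noise
    independently per (task, run, condition); condition mean amplitudes
    are added as constant offsets (they shift means, not correlations).
    Deterministic given ``seed``.
    """
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = root.spawn(n_participants)
    out: PatternSet = {}
    for p, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        pid = f"sub-{p + 1:03d}"
        out[pid] = {}
        for roi_label, gt in ground_truth.rois.items():
            nv = gt.n_voxels
            shared = rng.normal(0.0, np.sqrt(gt.sigma_shared2), nv)
            task_pat = {
                task: rng.normal(0.0, np.sqrt(gt.sigma_task2[task]), nv)
                for task in ANALYSIS_CONDITIONS
            }
            maps: dict[tuple[str, int, str], np.ndarray] = {}
            for task, conds in ANALYSIS_CONDITIONS.items():
                for run in range(1, n_runs + 1):
                    for cond in conds:
                        noise = rng.normal(0.0, np.sqrt(gt.sigma_run2), nv)
                        amp = ground_truth.condition_amplitudes.get(cond, 0.0)
                        maps[(task, run, cond)] = amp + shared + task_pat[task] + noise
            out[pid][roi_label] = maps
    return out
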