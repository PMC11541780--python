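"""End-to-end synthetic-cohort pipeline.

One seeded run chains the stages: simulate designs and behavior →
behavioral and motion screening → voxel patterns (or a full BOLD + GLM
round per participant when ``use_bold``) → top-N feature selection →
split-run correlation profiles → group inference and outcome
classification.  All randomness flows from a single root seed through
named per-participant substreams, so a seed fully determines the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .behavior import DEFAULT_ACCURACY, simulate_behavior
from .bold import MotionSpec, simulate_motion_trace
from .design import (
    DEFAULT_ITI_MENU,
    DEFAULT_REPETITION_TIME,
    DEFAULT_RESPONSE_WINDOW,
    DEFAULT_SENTENCE_DURATION_RANGE,
    GRAMMATICALITY,
    PLAUSIBILITY,
    build_task_design,
)
from .inference import SpecializationAnalysis
from .motion import detect_outlier_volumes, motion_pass
from .mvpa import SENTENCE_TYPE_CONDITIONS, correlation_profile, profiles_to_frame
from .patterns import GroundTruth, RoiGroundTruth, simulate_patterns
from .roi import TopVoxelSelector
from .screening import apply_inclusion, compute_performance

logger = logging.getLogger("sentspec.pipeline")


class DesignParams(BaseModel):
    n_runs: int = 2
    trials_per_condition: int = 20
    sentence_duration_range: tuple[float, float] = DEFAULT_SENTENCE_DURATION_RANGE
    response_window: float = DEFAULT_RESPONSE_WINDOW
    iti_menu: tuple[float, ...] = DEFAULT_ITI_MENU
    repetition_time: float = DEFAULT_REPETITION_TIME


class RoiTruthParams(BaseModel):
    sigma_shared2: float = 1.0
    sigma_task2_syntactic: float = 0.0
    sigma_task2_semantic: float = 0.0
    sigma_run2: float = 2.0
    n_voxels: int = 300


class Thresholds(BaseModel):
    """Every screening/analysis constant, with its conventional default."""

    accuracy_floor_pct: float = 50.0
    bias_limit_pct: float = 40.0
    motion_mm: float = 1.5
    signal_frac: float = 0.04
    outlier_fraction: float = 0.10
    max_consecutive_outliers: int = 6
    top_n: int = 250
    highpass_cutoff_s: float = 128.0
    alpha: float = 0.05
    bonferroni_m: int = 3


class RunConfig(BaseModel):
    seed: int = 0
    n_participants: int = 8
    design: DesignParams = Field(default_factory=DesignParams)
    rois: dict[str, RoiTruthParams] = Field(
        default_factory=lambda: {
            "IFG_opercularis": RoiTruthParams(sigma_task2_syntactic=1.0),
            "IFG_triangularis": RoiTruthParams(sigma_task2_syntactic=1.0, sigma_task2_semantic=1.0),
            "STG": RoiTruthParams(sigma_task2_syntactic=1.0, sigma_task2_semantic=1.0),
            "MTG": RoiTruthParams(sigma_task2_syntactic=1.0, sigma_task2_semantic=1.0),
        }
    )
    accuracy_by_condition: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_ACCURACY))
    motion_spike_rate: float = 0.0
    thresholds: Thresholds = Field(default_factory=Thresholds)
    sentence_types: tuple[str, ...] = ("correct", "incorrect")

    def ground_truth(self) -> GroundTruth:
        return GroundTruth(
            rois={
                name: RoiGroundTruth(
                    sigma_shared2=p.sigma_shared2,
                    sigma_task2={GRAMMATICALITY: p.sigma_task2_syntactic,
                                 PLAUSIBILITY: p.sigma_task2_semantic},
                    sigma_run2=p.sigma_run2,
                    n_voxels=p.n_voxels,
                )
                for name, p in self.rois.items()
            }
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full synthetic pipeline; returns the machine-readable report."""
    root = np.random.SeedSequence(config.seed)
    ss_design, ss_behavior, ss_motion, ss_patterns = root.spawn(4)
    thr = config.thresholds
    dp = config.design

    logger.info("stage=design building task designs for %d participants", config.n_participants)
    designs_by_participant = {}
    for p, ss in enumerate(ss_design.spawn(config.n_participants)):
        pid = f"sub-{p + 1:03d}"
        ss_g, ss_p = ss.spawn(2)
        designs_by_participant[pid] = {
            GRAMMATICALITY: build_task_design(
                GRAMMATICALITY, n_runs=dp.n_runs, trials_per_condition=dp.trials_per_condition,
                sentence_duration_range=dp.sentence_duration_range,
                response_window=dp.response_window, iti_menu=dp.iti_menu,
                repetition_time=dp.repetition_time, seed=ss_g),
            PLAUSIBILITY: build_task_design(
                PLAUSIBILITY, n_runs=dp.n_runs, trials_per_condition=dp.trials_per_condition,
                sentence_duration_range=dp.sentence_duration_range,
                response_window=dp.response_window, iti_menu=dp.iti_menu,
                repetition_time=dp.repetition_time, seed=ss_p),
        }

    logger.info("stage=screen simulating behavior and motion, applying inclusion")
    included: list[str] = []
    excluded_by: dict[str, int] = {}
    flagged_volumes = 0
    behav_streams = ss_behavior.spawn(config.n_participants)
    motion_streams = ss_motion.spawn(config.n_participants)
    for p, pid in enumerate(designs_by_participant):
        perf = {}
        b_rng = np.random.default_rng(behav_streams[p])
        for task, runs in designs_by_participant[pid].items():
            perf[task] = [
                compute_performance(
                    simulate_behavior(d, config.accuracy_by_condition, seed=b_rng.integers(2**31)),
                    d,
                )
                for d in runs
            ]
        m_rng = np.random.default_rng(motion_streams[p])
        motion_ok = []
        for task, runs in designs_by_participant[pid].items():
            for d in runs:
                n_vols = d.n_volumes
                spikes = tuple(
                    (int(v), int(m_rng.integers(0, 3)), 2.0)
                    for v in m_rng.integers(1, n_vols, size=m_rng.poisson(config.motion_spike_rate))
                )
                trace = simulate_motion_trace(n_vols, MotionSpec(spikes=spikes),
                                              seed=m_rng.integers(2**31))
                flags = detect_outlier_volumes(trace, motion_threshold=thr.motion_mm)
                flagged_volumes += flags.n_flagged
                motion_ok.append(motion_pass(flags, n_vols, thr.outlier_fraction,
                                             thr.max_consecutive_outliers))
        decision = apply_inclusion(
            perf, handedness_right_items=5, dialect_ok=True,
            nonverbal_score=100.0, language_score=100.0, motion_ok_by_run=motion_ok,
            accuracy_floor=thr.accuracy_floor_pct, bias_limit=thr.bias_limit_pct,
        )
        if decision.included:
            included.append(pid)
        else:
            for c in decision.failed_criteria:
                excluded_by[c] = excluded_by.get(c, 0) + 1

    if len(included) < 2:
        raise RuntimeError(f"stage=screen: only {len(included)} participants included")

    logger.info("stage=patterns simulating voxel patterns for %d included participants",
                len(included))
    all_patterns = simulate_patterns(config.ground_truth(), config.n_participants,
                                     n_runs=dp.n_runs, seed=ss_patterns)

    logger.info("stage=mvpa selecting features and computing correlation profiles")
    profiles = []
    voxels_selected = 0
    for pid in included:
        for roi_label, maps in all_patterns[pid].items():
            # selection map: pooled mean over every task/run/condition map
            # (stands in for the all-sentences minus control contrast)
            selection = np.mean(list(maps.values()), axis=0)
            selector = TopVoxelSelector(n=thr.top_n).fit(selection, _FullRoi(roi_label, selection.size))
            voxels_selected += selector.indices_.size
            for stype in config.sentence_types:
                syn_cond, sem_cond = SENTENCE_TYPE_CONDITIONS[stype]
                vectors = {
                    (GRAMMATICALITY, r): selector.transform(maps[(GRAMMATICALITY, r, syn_cond)])
                    for r in (1, 2)
                }
                vectors.update({
                    (PLAUSIBILITY, r): selector.transform(maps[(PLAUSIBILITY, r, sem_cond)])
                    for r in (1, 2)
                })
                profiles.append(correlation_profile(vectors, stype, participant=pid,
                                                    roi_label=roi_label))

    logger.info("stage=group paired inference over %d profiles", len(profiles))
    frame = profiles_to_frame(profiles)
    analysis = SpecializationAnalysis(alpha=thr.alpha, m=thr.bonferroni_m).fit(frame)

    report = {
        "software_version": __version__,
        "config_hash": config.config_hash(),
        "config": config.model_dump(mode="json"),
        "counts": {
            "n_participants": config.n_participants,
            "n_included": len(included),
            "excluded_by_criterion": excluded_by,
            "volumes_flagged": int(flagged_volumes),
            "voxels_selected": int(voxels_selected),
        },
        "outcomes": analysis.outcomes_.to_dict(orient="records"),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "profiles.tsv", sep="\t", index=False)
        analysis.outcomes_.to_csv(out / "outcomes.tsv", sep="\t", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


class _FullRoi:
    """Whole-vector pseudo-ROI for pattern-level (non-volumetric) data."""

    def __init__(self, roi_label: str, n: int):
        self.roi_label = roi_label
        self.indices = np.arange(n)
        self.shape = (n,)
        self.size = n
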