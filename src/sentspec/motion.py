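"""Outlier-volume detection, interpolation repair, and de-weighting.

A volume is an outlier when any translation parameter moves by more than
1.5 mm from the previous volume, or when its global mean signal (within a
brain mask) deviates from the run's global mean by more than 4%.  Outlier
volumes are replaced by linear interpolation between the nearest good
neighbours and given weight 0.01 (versus 1.0) in the first-level weighted
least squares, rather than being censored.  A run passes motion screening
when no more than 10% of its volumes, and no more than 6 consecutive
volumes, are outliers.

The 1.5 mm rule is applied to the three translation parameters only;
rotations (radians) can optionally be converted at an assumed head radius
via ``rotation_radius_mm``, off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

MOTION_THRESHOLD_MM = 1.5
SIGNAL_THRESHOLD_FRAC = 0.04
OUTLIER_FRACTION_LIMIT = 0.10
MAX_CONSECUTIVE_OUTLIERS = 6
OUTLIER_WEIGHT = 0.01
MASK_THRESHOLD = 0.5


@dataclass
class OutlierFlags:
    flagged: np.ndarray  # bool per volume
    reason: list[str]  # "", "motion", "signal", "both"

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())

    @property
    def max_consecutive(self) -> int:
        best = run = 0
        for f in self.flagged:
            run = run + 1 if f else 0
            best = max(best, run)
        return best


def _global_signal(series: np.ndarray, mask_threshold: float = MASK_THRESHOLD) -> np.ndarray:
    """Per-volume mean within a brain mask (voxel mean > 0.5 x grand mean)."""
    vox_mean = series.mean(axis=0)
    mask = vox_mean > mask_threshold * vox_mean.mean()
    if not mask.any():
        mask = np.ones(series.shape[1], dtype=bool)
    return series[:, mask].mean(axis=1)


def detect_outlier_volumes(
    motion_trace: np.ndarray,
    series: np.ndarray | None = None,
    motion_threshold: float = MOTION_THRESHOLD_MM,
    signal_threshold: float = SIGNAL_THRESHOLD_FRAC,
    rotation_radius_mm: float | None = None,
) -> OutlierFlags:
    """Flag volumes by the motion and (if a series is given) signal rules.

    The first volume is exempt from the motion rule (no predecessor).
    """
    trace = np.asarray(motion_trace, dtype=float)
    n = trace.shape[0]
    if series is not None and series.shape[0] != n:
        raise ValueError(f"motion trace rows ({n}) != volumes ({series.shape[0]})")

    disp = np.abs(np.diff(trace[:, :3], axis=0))
    motion_flag = np.zeros(n, dtype=bool)
    motion_flag[1:] = (disp > motion_threshold).any(axis=1)
    if rotation_radius_mm is not None:
        rot_disp = np.abs(np.diff(trace[:, 3:6], axis=0)) * rotation_radius_mm
        motion_flag[1:] |= (rot_disp > motion_threshold).any(axis=1)

    signal_flag = np.zeros(n, dtype=bool)
    if series is not None:
        g = _global_signal(np.asarray(series, dtype=float))
        ref = g.mean()
        signal_flag = np.abs(g - ref) / ref > signal_threshold

    flagged = motion_flag | signal_flag
    reason = [
        "both" if m and s else "motion" if m else "signal" if s else ""
        for m, s in zip(motion_flag, signal_flag)
    ]
    return OutlierFlags(flagged=flagged, reason=reason)


def repair_and_weight(
    series: np.ndarray, flags: OutlierFlags
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate flagged volumes from adjacent good ones; build weights.

    Interior outliers are replaced voxelwise by linear interpolation
    between the nearest preceding and following good volumes; outliers at
    a run boundary copy the nearest good volume.  Unflagged volumes are
    untouched.  Weights are 1.0 (good) or 0.01 (repaired).
    """
    y = np.array(series, dtype=float, copy=True)
    flagged = flags.flagged
    if flagged.shape[0] != y.shape[0]:
        raise ValueError("flags length != volume count")
    good = np.flatnonzero(~flagged)
    if good.size == 0:
        raise ValueError("all volumes flagged; nothing to interpolate from")
    for t in np.flatnonzero(flagged):
        prev = good[good < t]
        nxt = good[good > t]
        if prev.size and nxt.size:
            a, b = prev[-1], nxt[0]
            frac = (t - a) / (b - a)
            y[t] = (1.0 - frac) * y[a] + frac * y[b]
        else:
            y[t] = y[prev[-1] if prev.size else nxt[0]]
    weights = np.where(flagged, OUTLIER_WEIGHT, 1.0)
    return y, weights


def motion_pass(flags: OutlierFlags, n_volumes: int,
                fraction_limit: float = OUTLIER_FRACTION_LIMIT,
                max_consecutive: int = MAX_CONSECUTIVE_OUTLIERS) -> bool:
    """Run-level screen: <=10% outliers and <=6 consecutive outliers."""
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    return (flags.n_flagged <= fraction_limit * n_volumes
            and flags.max_consecutive <= max_consecutive)


class MotionRepair(BaseEstimator, TransformerMixin):
    """Detect-and-repair transformer for one run's volume series.

    ``fit(series, motion_trace=...)`` detects outliers and stores
    ``flags_`` and ``weights_``; ``transform(series)`` returns the
    repaired series.
    """

    def __init__(self, motion_threshold: float = MOTION_THRESHOLD_MM,
                 signal_threshold: float = SIGNAL_THRESHOLD_FRAC,
                 rotation_radius_mm: float | None = None):
        self.motion_threshold = motion_threshold
        self.signal_threshold = signal_threshold
        self.rotation_radius_mm = rotation_radius_mm

    def fit(self, series: np.ndarray, motion_trace: np.ndarray | None = None) -> "MotionRepair":
        if motion_trace is None:
            motion_trace = np.zeros((series.shape[0], 6))
        self.flags_ = detect_outlier_volumes(
            motion_trace, series,
            motion_threshold=self.motion_threshold,
            signal_threshold=self.signal_threshold,
            rotation_radius_mm=self.rotation_radius_mm,
        )
        _, self.weights_ = repair_and_weight(series, self.flags_)
        return self

    def transform(self, series: np.ndarray) -> np.ndarray:
        repaired, _ = repair_and_weight(series, self.flags_)
        return repaired
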