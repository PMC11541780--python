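"""Forward BOLD simulation: the GLM's generative model plus drift,
noise, and injectable head-motion spikes.

The simulated series is

    y(t) = baseline + sum_c beta_c * x_c(t) + drift(t) + noise(t)

where x_c are the same canonical-HRF-convolved condition regressors the
first-level GLM uses, so a noiseless simulation round-trips through the
GLM exactly.  The motion trace is a smooth random walk in six parameters
(translations in mm, rotations in rad) with optional step displacements
at chosen volumes, for exercising outlier detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import TaskDesign
from .glm import _condition_regressor, dct_basis


@dataclass(frozen=True)
class DriftSpec:
    """Low-frequency drift: amplitudes on the slowest cosine regressors."""

    amplitudes: tuple[float, ...] = ()
    cutoff: float = 128.0


@dataclass(frozen=True)
class MotionSpec:
    """Baseline wander plus step displacements ("spikes").

    ``spikes`` maps volume index -> (axis, size): a sustained step of
    ``size`` (mm for axes 0-2, rad for 3-5) from that volume on, i.e. a
    sudden head repositioning.
    """

    wander_sd: float = 0.02
    spikes: tuple[tuple[int, int, float], ...] = ()  # (volume, axis, size)


def simulate_motion_trace(n_volumes: int, motion_spec: MotionSpec | None = None,
                          seed: int | np.random.SeedSequence | None = None) -> np.ndarray:
    """Six-parameter realignment trace, one row per volume."""
    spec = motion_spec or MotionSpec()
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, spec.wander_sd, size=(n_volumes, 6))
    steps[0] = 0.0
    trace = np.cumsum(steps, axis=0)
    for vol, axis, size in spec.spikes:
        trace[vol:, axis] += size
    return trace


@dataclass
class VolumeSeries:
    """4D series flattened to (n_volumes, n_voxels) with its TR."""

    data: np.ndarray
    repetition_time: float
    shape3d: tuple[int, int, int] | None = None

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]


def simulate_bold_run(
    design: TaskDesign,
    voxel_betas: dict[str, np.ndarray],
    noise_sd: float = 0.0,
    baseline: float = 100.0,
    drift_spec: DriftSpec | None = None,
    motion_spec: MotionSpec | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[VolumeSeries, np.ndarray]:
    """Simulate one run: returns (series, motion trace).

    ``voxel_betas`` maps each condition to its per-voxel amplitude vector;
    all vectors must share one length.  Deterministic given ``seed``.
    """
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_noise, rng_motion = (np.random.default_rng(s) for s in root.spawn(2))
    tr = design.repetition_time
    n_vols = design.n_volumes
    sizes = {b.shape for b in map(np.asarray, voxel_betas.values())}
    if len(sizes) != 1:
        raise ValueError("all voxel_betas vectors must have the same length")
    (n_voxels,) = sizes.pop()

    y = np.full((n_vols, n_voxels), float(baseline))
    for cond, betas in voxel_betas.items():
        onsets = np.array([t.onset for t in design.trials if t.condition == cond])
        if onsets.size == 0:
            continue
        durs = np.array([t.sentence_duration for t in design.trials if t.condition == cond])
        reg = _condition_regressor(onsets, durs, n_vols, tr)
        y += np.outer(reg, np.asarray(betas, dtype=float))

    if drift_spec and drift_spec.amplitudes:
        basis = dct_basis(n_vols, tr, drift_spec.cutoff)
        k = min(len(drift_spec.amplitudes), basis.shape[1])
        y += (basis[:, :k] @ np.asarray(drift_spec.amplitudes[:k]))[:, None]

    if noise_sd > 0:
        y += rng_noise.normal(0.0, noise_sd, size=y.shape)

    trace = simulate_motion_trace(n_vols, motion_spec, seed=rng_motion)
    return VolumeSeries(data=y, repetition_time=tr), trace
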