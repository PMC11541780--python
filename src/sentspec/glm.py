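"""First-level GLM: design matrices, weighted least squares, contrast t-maps.

Per-run design matrices contain one canonical-HRF-convolved indicator per
condition (duration = sentence duration), the six realignment parameters,
a discrete-cosine drift basis implementing a 128 s high-pass cutoff, and
an intercept.  Fitting is voxelwise weighted least squares so that
repaired outlier volumes can be de-weighted (weight 0.01) rather than
censored.  Each run is fit separately, which yields the per-run contrast
t-maps (condition minus perceptual control) that the split-run pattern
correlations require.

Serial-correlation prewhitening (AR(1)) is deliberately omitted: t-maps
enter the analysis only through spatial correlations, which are invariant
to the map-wide scaling that whitening would change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .design import TaskDesign

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")
DEFAULT_HIGHPASS_CUTOFF = 128.0
DEFAULT_MASK_THRESHOLD = 0.5

#: canonical double-gamma HRF parameters: response peak delay, undershoot
#: delay (gamma shape parameters at unit dispersion) and peak:undershoot ratio
HRF_PEAK_DELAY = 6.0
HRF_UNDERSHOOT_DELAY = 16.0
HRF_RATIO = 6.0
HRF_LENGTH = 32.0
_OVERSAMPLE = 16


class RankDeficientDesignError(np.linalg.LinAlgError):
    """Design matrix is rank-deficient in its regressors of interest."""


def hrf(t: np.ndarray, peak_delay: float = HRF_PEAK_DELAY,
        undershoot_delay: float = HRF_UNDERSHOOT_DELAY, ratio: float = HRF_RATIO) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at times t (s)."""
    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, peak_delay) - stats.gamma.pdf(t, undershoot_delay) / ratio
    h[t < 0] = 0.0
    return h


def _condition_regressor(onsets: np.ndarray, durations: np.ndarray,
                         n_volumes: int, tr: float) -> np.ndarray:
    """HRF-convolved boxcar sampled at volume acquisition times."""
    dt = tr / _OVERSAMPLE
    n_fine = int(np.ceil((n_volumes * tr + HRF_LENGTH) / dt)) + 1
    box = np.zeros(n_fine)
    grid = np.arange(n_fine) * dt
    for on, dur in zip(onsets, durations):
        box[(grid >= on) & (grid < on + dur)] = 1.0
    kernel = hrf(np.arange(0.0, HRF_LENGTH, dt))
    conv = np.convolve(box, kernel)[:n_fine] * dt
    sample_idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)
    return conv[sample_idx]


def dct_drift_count(run_duration: float, cutoff: float = DEFAULT_HIGHPASS_CUTOFF) -> int:
    """Number of cosine drift regressors for a high-pass cutoff (floor(2T/c))."""
    return int(np.floor(2.0 * run_duration / cutoff))


def dct_basis(n_volumes: int, tr: float, cutoff: float = DEFAULT_HIGHPASS_CUTOFF) -> np.ndarray:
    """Unit-norm discrete cosine drift regressors below 1/cutoff Hz."""
    k = dct_drift_count(n_volumes * tr, cutoff)
    n = np.arange(n_volumes)
    cols = [np.sqrt(2.0 / n_volumes) * np.cos(np.pi * (2 * n + 1) * j / (2 * n_volumes))
            for j in range(1, k + 1)]
    return np.column_stack(cols) if cols else np.empty((n_volumes, 0))


@dataclass
class DesignMatrix:
    """Labeled design matrix with bookkeeping of regressors of interest."""

    frame: pd.DataFrame
    condition_columns: tuple[str, ...]
    dropped_columns: tuple[str, ...] = ()

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    def contrast_vector(self, weights: dict[str, float]) -> np.ndarray:
        unknown = set(weights) - set(self.columns)
        if unknown:
            raise KeyError(f"unknown regressors in contrast: {sorted(unknown)}")
        return np.array([weights.get(c, 0.0) for c in self.columns])


def build_design_matrix(
    design: TaskDesign,
    motion_trace: np.ndarray | None = None,
    n_volumes: int | None = None,
    highpass_cutoff: float = DEFAULT_HIGHPASS_CUTOFF,
    hrf_params: dict[str, float] | None = None,
) -> DesignMatrix:
    """Assemble the per-run design matrix for one task run.

    Nuisance columns that do not increase the matrix rank (e.g. a constant
    motion parameter, collinear with the intercept) are dropped and
    recorded in ``dropped_columns``; rank deficiency among condition
    regressors is an error.
    """
    tr = design.repetition_time
    if n_volumes is None:
        n_volumes = design.n_volumes
    last = design.trials[-1]
    if last.onset + last.sentence_duration > n_volumes * tr:
        raise ValueError("design extends beyond the acquired volume series")
    if motion_trace is not None:
        motion_trace = np.asarray(motion_trace, dtype=float)
        if motion_trace.shape[0] != n_volumes:
            raise ValueError(
                f"motion trace rows ({motion_trace.shape[0]}) != volumes ({n_volumes})"
            )

    cols: dict[str, np.ndarray] = {}
    conditions = design.conditions
    params = hrf_params or {}
    for cond in conditions:
        onsets = np.array([t.onset for t in design.trials if t.condition == cond])
        durs = np.array([t.sentence_duration for t in design.trials if t.condition == cond])
        reg = _condition_regressor(onsets, durs, n_volumes, tr)
        if params:  # custom HRF: re-convolve with given parameters
            dt = tr / _OVERSAMPLE
            n_fine = int(np.ceil((n_volumes * tr + HRF_LENGTH) / dt)) + 1
            box = np.zeros(n_fine)
            grid = np.arange(n_fine) * dt
            for on, dur in zip(onsets, durs):
                box[(grid >= on) & (grid < on + dur)] = 1.0
            kernel = hrf(np.arange(0.0, HRF_LENGTH, dt), **params)
            conv = np.convolve(box, kernel)[:n_fine] * dt
            reg = conv[np.round(np.arange(n_volumes) * tr / dt).astype(int)]
        cols[cond] = reg

    X_cond = np.column_stack(list(cols.values()))
    if np.linalg.matrix_rank(X_cond) < X_cond.shape[1]:
        raise RankDeficientDesignError(
            f"condition regressors are linearly dependent: {conditions}"
        )

    drift = dct_basis(n_volumes, tr, highpass_cutoff)
    drift_names = [f"drift_{j + 1}" for j in range(drift.shape[1])]
    nuisance: list[tuple[str, np.ndarray]] = []
    if motion_trace is not None:
        nuisance += list(zip(MOTION_COLUMNS, motion_trace.T))
    nuisance += list(zip(drift_names, drift.T))
    nuisance.append(("intercept", np.ones(n_volumes)))

    # greedy rank repair: keep intercept/drift/motion columns only while
    # they add rank on top of the condition regressors
    kept, dropped = [], []
    base = X_cond
    rank = np.linalg.matrix_rank(base)
    # intercept first so constant nuisance columns are the ones dropped
    for name, col in sorted(nuisance, key=lambda nc: nc[0] != "intercept"):
        cand = np.column_stack([base, col])
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            kept.append((name, col))
            base, rank = cand, r
        else:
            dropped.append(name)

    order = list(conditions) + [n for n, _ in nuisance if n in {k for k, _ in kept}]
    data = dict(cols)
    data.update(dict(kept))
    frame = pd.DataFrame({name: data[name] for name in order})
    return DesignMatrix(frame=frame, condition_columns=tuple(conditions),
                        dropped_columns=tuple(dropped))


@dataclass
class ContrastTMap:
    """Voxelwise t-statistics for one contrast of a fitted run."""

    t: np.ndarray
    contrast: np.ndarray
    df: int
    mask: np.ndarray  # in-analysis-mask indicator; t is NaN outside

    @property
    def values(self) -> np.ndarray:
        return self.t


class FirstLevelGLM(BaseEstimator):
    """Voxelwise weighted least-squares GLM for one run.

    Parameters
    ----------
    mask_threshold : float
        Analysis-mask rule: a voxel is analyzed when its temporal mean
        exceeds ``mask_threshold`` times the grand mean over voxels
        (the conventional 0.5 "artificial mask").
    """

    def __init__(self, mask_threshold: float = DEFAULT_MASK_THRESHOLD):
        self.mask_threshold = mask_threshold

    def fit(self, series: np.ndarray, design_matrix: DesignMatrix,
            weights: np.ndarray | None = None) -> "FirstLevelGLM":
        """Fit y = X beta voxelwise with per-volume weights.

        series : (n_volumes, n_voxels); weights : (n_volumes,) in (0, 1].
        """
        y = np.asarray(series, dtype=float)
        X = design_matrix.values
        n, p = X.shape
        if y.shape[0] != n:
            raise ValueError(f"series has {y.shape[0]} volumes, design has {n} rows")
        if weights is None:
            w = np.ones(n)
        else:
            w = np.asarray(weights, dtype=float)
            if w.shape != (n,):
                raise ValueError("weights length must equal design rows")
            if np.any(w <= 0):
                raise ValueError("weights must be positive")

        rank = np.linalg.matrix_rank(X)
        if rank < p:
            dep = _dependent_columns(X, design_matrix.columns)
            raise RankDeficientDesignError(f"design matrix rank-deficient; dependent columns: {dep}")

        xtwx = X.T @ (w[:, None] * X)
        xtwx_inv = np.linalg.inv(xtwx)
        beta = xtwx_inv @ (X.T @ (w[:, None] * y))
        resid = y - X @ beta
        df = int(n - rank)
        sigma2 = (w[:, None] * resid**2).sum(axis=0) / df

        vox_mean = y.mean(axis=0)
        grand = vox_mean.mean()
        mask = vox_mean > self.mask_threshold * grand

        self.design_matrix_ = design_matrix
        self.weights_ = w
        self.betas_ = beta
        self.sigma2_ = sigma2
        self.df_ = df
        self.mask_ = mask
        self.xtwx_inv_ = xtwx_inv
        return self

    def contrast(self, contrast: np.ndarray | dict[str, float]) -> ContrastTMap:
        """t-map for a contrast vector (or {regressor: weight} mapping)."""
        if isinstance(contrast, dict):
            c = self.design_matrix_.contrast_vector(contrast)
        else:
            c = np.asarray(contrast, dtype=float)
        if c.shape != (self.betas_.shape[0],):
            raise ValueError("contrast length must equal number of regressors")
        if not np.any(c):
            raise ValueError("contrast vector is all zeros")
        effect = c @ self.betas_
        var_c = float(c @ self.xtwx_inv_ @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = effect / np.sqrt(var_c * self.sigma2_)
        t = np.where(self.mask_, t, np.nan)
        return ContrastTMap(t=t, contrast=c, df=self.df_, mask=self.mask_)


def _dependent_columns(X: np.ndarray, names: tuple[str, ...]) -> list[str]:
    kept: list[int] = []
    dep: list[str] = []
    rank = 0
    for j in range(X.shape[1]):
        r = np.linalg.matrix_rank(X[:, kept + [j]])
        if r > rank:
            kept.append(j)
            rank = r
        else:
            dep.append(names[j])
    return dep


def fit_weighted_glm(series: np.ndarray, design_matrix: DesignMatrix,
                     weights: np.ndarray | None = None,
                     mask_threshold: float = DEFAULT_MASK_THRESHOLD) -> FirstLevelGLM:
    """Functional wrapper over :class:`FirstLevelGLM`."""
    return FirstLevelGLM(mask_threshold=mask_threshold).fit(series, design_matrix, weights)


def condition_contrast(design_matrix: DesignMatrix, positive: str, negative: str) -> np.ndarray:
    """Simple contrast vector: +1 on ``positive``, -1 on ``negative``."""
    return design_matrix.contrast_vector({positive: 1.0, negative: -1.0})


def simple_contrasts(design_matrix: DesignMatrix, control: str = "PC") -> dict[str, np.ndarray]:
    """Per-condition (condition minus control) contrasts for one run."""
    return {
        f"{cond}-{control}": condition_contrast(design_matrix, cond, control)
        for cond in design_matrix.condition_columns
        if cond != control
    }


def all_sentences_vs_control_contrast(design_matrix: DesignMatrix, control: str = "PC") -> np.ndarray:
    """Mean of sentence conditions minus control (feature-selection contrast)."""
    sent = [c for c in design_matrix.condition_columns if c != control]
    if not sent:
        raise ValueError("no sentence conditions besides the control")
    weights = {c: 1.0 / len(sent) for c in sent}
    weights[control] = -1.0
    return design_matrix.contrast_vector(weights)
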