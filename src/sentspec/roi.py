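"""Region-of-interest masks and top-N voxel feature selection.

The analysis uses four left-hemisphere language regions (IFG pars
opercularis, IFG pars triangularis, STG, MTG) supplied as an anatomical
label volume.  Each region mask is the intersection of its anatomical
label with the coverage of the analyzed data (the degenerate "threshold
p = 1" functional map).  Within each region, each participant's features
are the N most activated voxels (largest t for the pooled all-sentences
minus perceptual-control contrast), regardless of significance, with
ties broken by ascending voxel index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

ROI_LABELS = ("IFG_opercularis", "IFG_triangularis", "STG", "MTG")
DEFAULT_TOP_N = 250


class GridMismatchError(ValueError):
    """Volumes are not on the same grid."""


@dataclass(frozen=True)
class RoiMask:
    """Flat voxel indices of one region within a 3D grid."""

    roi_label: str
    indices: np.ndarray
    shape: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices)
        n = int(np.prod(self.shape))
        if idx.size == 0:
            raise ValueError(f"ROI {self.roi_label!r} is empty")
        if idx.min() < 0 or idx.max() >= n:
            raise ValueError("voxel indices outside the volume grid")

    @property
    def size(self) -> int:
        return len(self.indices)


def build_roi_mask(
    anatomical_labels: np.ndarray,
    label_value: int,
    coverage: np.ndarray,
    roi_label: str,
) -> RoiMask:
    """Anatomical region intersected with analyzed-voxel coverage."""
    anatomical_labels = np.asarray(anatomical_labels)
    coverage = np.asarray(coverage)
    if anatomical_labels.shape != coverage.shape:
        raise GridMismatchError(
            f"label volume {anatomical_labels.shape} and coverage {coverage.shape} differ"
        )
    joint = (anatomical_labels == label_value) & coverage.astype(bool)
    idx = np.flatnonzero(joint.ravel())
    if idx.size == 0:
        raise ValueError(f"ROI {roi_label!r}: anatomical label {label_value} has no covered voxels")
    return RoiMask(roi_label=roi_label, indices=idx, shape=anatomical_labels.shape)


@dataclass
class FeatureSet:
    """A participant's selected voxels in one region, most active first."""

    roi_label: str
    participant: str
    indices: np.ndarray  # sorted by descending selection t, ties by index
    tvalues: np.ndarray


class TopVoxelSelector(BaseEstimator):
    """Select the ``n`` most activated in-region voxels of a selection map.

    ``fit(selection_map, roi=...)`` ranks the region's voxels by the
    selection statistic (descending; ties broken by ascending voxel
    index); ``transform(map)`` extracts any map's values at the selected
    voxels in that canonical order.
    """

    def __init__(self, n: int = DEFAULT_TOP_N):
        self.n = n

    def fit(self, selection_map: np.ndarray, roi: RoiMask) -> "TopVoxelSelector":
        flat = np.asarray(selection_map, dtype=float).ravel()
        tvals = flat[roi.indices]
        defined = np.isfinite(tvals)
        if not defined.any():
            raise ValueError(
                f"selection map undefined on every voxel of ROI {roi.roi_label!r}"
            )
        cand_idx = roi.indices[defined]
        cand_t = tvals[defined]
        if cand_idx.size < self.n:
            warnings.warn(
                f"ROI {roi.roi_label!r} has only {cand_idx.size} usable voxels "
                f"(< n={self.n}); selecting all",
                stacklevel=2,
            )
        # stable sort on ascending index first, then descending t
        order = np.argsort(cand_idx, kind="stable")
        order = order[np.argsort(-cand_t[order], kind="stable")]
        keep = order[: self.n]
        self.roi_ = roi
        self.indices_ = cand_idx[keep]
        self.tvalues_ = cand_t[keep]
        return self

    def transform(self, volume_map: np.ndarray) -> np.ndarray:
        flat = np.asarray(volume_map, dtype=float).ravel()
        values = flat[self.indices_]
        if not np.isfinite(values).all():
            bad = self.indices_[~np.isfinite(values)]
            raise ValueError(f"map undefined at selected voxels {bad[:5].tolist()}...")
        return values


def select_top_voxels(selection_tmap, roi: RoiMask, n: int = DEFAULT_TOP_N,
                      participant: str = "") -> FeatureSet:
    """Functional wrapper over :class:`TopVoxelSelector`."""
    values = getattr(selection_tmap, "t", selection_tmap)
    sel = TopVoxelSelector(n=n).fit(values, roi)
    return FeatureSet(roi_label=roi.roi_label, participant=participant,
                      indices=sel.indices_, tvalues=sel.tvalues_)
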