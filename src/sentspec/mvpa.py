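"""Split-run pattern correlations within and across tasks.

For each participant, region, and sentence type (correct / incorrect),
three quantities are computed from the per-run contrast t-patterns over
the selected voxels:

* within-syntactic r — Pearson correlation of the syntactic-task
  condition pattern between run 1 and run 2 (Gram for correct
  sentences, FVio for incorrect);
* within-semantic r — the same for the semantic task (SCon / InCon);
* across-task r — the mean of the four run-pair correlations between
  the syntactic and semantic patterns (G1xP1, G1xP2, G2xP1, G2xP2).

Task-specialized regions show within-task correlations that exceed the
across-task correlation; regions representing the same information in
both tasks show all three at comparable levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import GRAMMATICALITY, PLAUSIBILITY
from .roi import FeatureSet

#: (syntactic condition, semantic condition) per sentence type
SENTENCE_TYPE_CONDITIONS: dict[str, tuple[str, str]] = {
    "correct": ("Gram", "SCon"),
    "incorrect": ("FVio", "InCon"),
    # exploratory pairing of the other violation condition
    "plurality": ("PVio", "InCon"),
}

#: the four across-task run pairings (syntactic run, semantic run)
ACROSS_PAIRS = ((1, 1), (1, 2), (2, 1), (2, 2))


class ZeroVarianceError(ValueError):
    """A pattern vector has no variance, so Pearson r is undefined."""


def extract_features(tmap, features: FeatureSet) -> np.ndarray:
    """Values of a t-map at the feature voxels, in canonical order."""
    values = np.asarray(getattr(tmap, "t", tmap), dtype=float).ravel()[features.indices]
    if not np.isfinite(values).all():
        raise ValueError(
            f"t-map undefined at {int((~np.isfinite(values)).sum())} feature voxels "
            f"of ROI {features.roi_label!r}"
        )
    return values


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if a.size < 3:
        raise ValueError("need at least 3 voxels to correlate")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class CorrelationProfile:
    participant: str
    roi_label: str
    sentence_type: str
    r_within_syntactic: float
    r_within_semantic: float
    r_across: float
    across_components: dict[tuple[int, int], float] = field(default_factory=dict)


def correlation_profile(
    vectors: dict[tuple[str, int], np.ndarray],
    sentence_type: str,
    participant: str = "",
    roi_label: str = "",
    fisher_z: bool = False,
) -> CorrelationProfile:
    """Within- and across-task correlations from four run patterns.

    ``vectors`` maps (task, run) — tasks ``grammaticality`` and
    ``plausibility``, runs 1 and 2 — to a feature-voxel t-vector.  With
    ``fisher_z`` the four across-task r's are averaged in Fisher-z space
    and back-transformed (default: plain arithmetic mean, matching how
    these correlations are conventionally reported).
    """
    keys = [(GRAMMATICALITY, 1), (GRAMMATICALITY, 2), (PLAUSIBILITY, 1), (PLAUSIBILITY, 2)]
    missing = [k for k in keys if k not in vectors]
    if missing:
        raise KeyError(f"missing pattern vectors for {missing}")
    lengths = {len(vectors[k]) for k in keys}
    if len(lengths) != 1:
        raise ValueError("all four pattern vectors must have the same length")
    for k in keys:
        v = np.asarray(vectors[k], dtype=float)
        if np.std(v) == 0:
            raise ZeroVarianceError(f"pattern for task={k[0]!r} run={k[1]} has zero variance")

    r_syn = pearson_r(vectors[(GRAMMATICALITY, 1)], vectors[(GRAMMATICALITY, 2)])
    r_sem = pearson_r(vectors[(PLAUSIBILITY, 1)], vectors[(PLAUSIBILITY, 2)])
    components = {
        (rg, rp): pearson_r(vectors[(GRAMMATICALITY, rg)], vectors[(PLAUSIBILITY, rp)])
        for rg, rp in ACROSS_PAIRS
    }
    rs = np.array(list(components.values()))
    if fisher_z:
        r_across = float(np.tanh(np.mean(np.arctanh(rs))))
    else:
        r_across = float(rs.mean())
    return CorrelationProfile(
        participant=participant, roi_label=roi_label, sentence_type=sentence_type,
        r_within_syntactic=r_syn, r_within_semantic=r_sem, r_across=r_across,
        across_components=components,
    )


def profiles_to_frame(profiles: list[CorrelationProfile]) -> pd.DataFrame:
    """Wide table: one row per participant x region x sentence type."""
    return pd.DataFrame(
        {
            "participant": [p.participant for p in profiles],
            "roi_label": [p.roi_label for p in profiles],
            "sentence_type": [p.sentence_type for p in profiles],
            "r_within_syntactic": [p.r_within_syntactic for p in profiles],
            "r_within_semantic": [p.r_within_semantic for p in profiles],
            "r_across": [p.r_across for p in profiles],
        }
    )
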