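"""Group-level paired inference and specialization-outcome classification.

Per region and sentence type, three paired t-tests compare the
participant-level correlations: within-syntactic vs. across-task,
within-semantic vs. across-task, and within-syntactic vs.
within-semantic.  p-values are two-tailed and Bonferroni-corrected
within the family of three comparisons (p_corrected = min(1, 3p)).
The corrected significance/direction pattern is then classified:

* strong syntactic/semantic specialization — only that task's
  within-task correlation exceeds the across-task correlation;
* weak specialization — both within-task correlations exceed across,
  and one within-task correlation exceeds the other;
* both, no specialization — both exceed across, within-task
  correlations indistinguishable;
* neither — no comparison significant;
* indeterminate — any other pattern (e.g. a significant reversed
  direction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

DEFAULT_ALPHA = 0.05
DEFAULT_BONFERRONI_M = 3

COMPARISONS = ("syn_vs_across", "sem_vs_across", "syn_vs_sem")
OUTCOMES = (
    "strong_syntactic", "weak_syntactic", "strong_semantic", "weak_semantic",
    "both_no_specialization", "neither", "indeterminate",
)


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p_uncorrected: float
    mean_diff: float
    p_bonferroni: float | None = None


def paired_t(x: np.ndarray, y: np.ndarray) -> PairedTResult:
    """Two-tailed paired t-test: t = mean(d) / (sd(d)/sqrt(n)), df = n-1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("paired differences have zero variance")
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return PairedTResult(t=float(t), df=df, p_uncorrected=float(p), mean_diff=float(d.mean()))


def bonferroni_adjust(p: float, m: int = DEFAULT_BONFERRONI_M) -> float:
    """min(1, m*p); the family is the three comparisons per cell."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


@dataclass
class GroupComparisonResult:
    """The three paired comparisons for one region x sentence type."""

    roi_label: str
    sentence_type: str
    comparisons: dict[str, PairedTResult]
    n_participants: int


def _comparison_state(res: PairedTResult, alpha: float) -> str:
    if res.p_bonferroni is None:
        raise ValueError("comparison lacks a corrected p-value")
    if res.p_bonferroni < alpha:
        return "pos" if res.mean_diff > 0 else "neg"
    return "ns"


def classify_states(syn: str, sem: str, syn_sem: str) -> str:
    """Map a significance/direction triple to an outcome label.

    Each state is ``pos`` (significant, first member larger), ``neg``
    (significant, reversed), or ``ns``.  The mapping is total over all
    27 triples.
    """
    if syn == "neg" or sem == "neg":
        return "indeterminate"
    if syn == "pos" and sem == "pos":
        return {"pos": "weak_syntactic", "neg": "weak_semantic",
                "ns": "both_no_specialization"}[syn_sem]
    if syn == "pos":  # sem ns
        return "indeterminate" if syn_sem == "neg" else "strong_syntactic"
    if sem == "pos":  # syn ns
        return "indeterminate" if syn_sem == "pos" else "strong_semantic"
    return "neither" if syn_sem == "ns" else "indeterminate"


def classify_outcome(result: GroupComparisonResult, alpha: float = DEFAULT_ALPHA) -> str:
    states = [_comparison_state(result.comparisons[c], alpha) for c in COMPARISONS]
    return classify_states(*states)


class SpecializationAnalysis(BaseEstimator):
    """Group analysis over a table of per-participant correlation profiles.

    ``fit`` expects the wide profile table (columns ``participant``,
    ``roi_label``, ``sentence_type``, ``r_within_syntactic``,
    ``r_within_semantic``, ``r_across``) and produces ``results_`` (the
    per-cell comparison statistics) and ``outcomes_`` (a tidy outcome
    table).  Participants with incomplete cells are dropped listwise per
    cell; the dropped counts are recorded in ``dropped_``.
    """

    def __init__(self, alpha: float = DEFAULT_ALPHA, m: int = DEFAULT_BONFERRONI_M):
        self.alpha = alpha
        self.m = m

    def fit(self, profiles: pd.DataFrame, y=None) -> "SpecializationAnalysis":
        required = {"participant", "roi_label", "sentence_type",
                    "r_within_syntactic", "r_within_semantic", "r_across"}
        missing = required - set(profiles.columns)
        if missing:
            raise ValueError(f"profile table lacks columns: {sorted(missing)}")

        results: list[GroupComparisonResult] = []
        rows = []
        dropped: dict[tuple[str, str], int] = {}
        for (roi, stype), cell in profiles.groupby(["roi_label", "sentence_type"], sort=True):
            if cell["participant"].duplicated().any():
                dups = cell.loc[cell["participant"].duplicated(), "participant"].tolist()
                raise ValueError(f"duplicate participant ids in cell ({roi}, {stype}): {dups}")
            complete = cell.dropna(subset=["r_within_syntactic", "r_within_semantic", "r_across"])
            dropped[(roi, stype)] = len(cell) - len(complete)
            if len(complete) < 2:
                raise ValueError(
                    f"cell ({roi}, {stype}) has {len(complete)} complete participants (< 2)"
                )
            syn = complete["r_within_syntactic"].to_numpy()
            sem = complete["r_within_semantic"].to_numpy()
            acr = complete["r_across"].to_numpy()
            comps = {}
            for name, (a, b) in zip(COMPARISONS, [(syn, acr), (sem, acr), (syn, sem)]):
                res = paired_t(a, b)
                comps[name] = PairedTResult(
                    t=res.t, df=res.df, p_uncorrected=res.p_uncorrected,
                    mean_diff=res.mean_diff,
                    p_bonferroni=bonferroni_adjust(res.p_uncorrected, self.m),
                )
            result = GroupComparisonResult(
                roi_label=roi, sentence_type=stype,
                comparisons=comps, n_participants=len(complete),
            )
            results.append(result)
            label = classify_outcome(result, self.alpha)
            row = {"roi_label": roi, "sentence_type": stype, "n": len(complete),
                   "outcome": label}
            for name, c in comps.items():
                row[f"{name}_t"] = c.t
                row[f"{name}_df"] = c.df
                row[f"{name}_p"] = c.p_uncorrected
                row[f"{name}_p_bonf"] = c.p_bonferroni
                row[f"{name}_mean_diff"] = c.mean_diff
            rows.append(row)

        self.results_ = results
        self.outcomes_ = pd.DataFrame(rows)
        self.dropped_ = dropped
        return self


def analyze_all(profiles: pd.DataFrame, alpha: float = DEFAULT_ALPHA,
                m: int = DEFAULT_BONFERRONI_M) -> pd.DataFrame:
    """Functional wrapper over :class:`SpecializationAnalysis`."""
    return SpecializationAnalysis(alpha=alpha, m=m).fit(profiles).outcomes_
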