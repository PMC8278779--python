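"""Cohort-level evaluation: confusion tables, mean scores with CIs,
sensitivity/specificity, and the dominant-spectral-type table.

Percentages always recompute from counts; confidence intervals are
two-sided Student-t intervals on the per-lesion scores (omitted for groups
with fewer than two lesions, where the interval is undefined).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import Decision, LesionScore
from .spectra import Diagnosis, SpectralType

__all__ = [
    "CohortMetrics",
    "confusion_counts",
    "mean_score_ci",
    "spectral_type_table",
    "dominant_type",
    "evaluate_cohort",
]

_BENIGN = (Diagnosis.SK, Diagnosis.NEVUS)


def mean_score_ci(
    scores: np.ndarray, level: float = 0.95
) -> tuple[float, float, float]:
    """Sample mean with a two-sided t-interval (n-1 degrees of freedom)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least two scores for a confidence interval")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    mean = float(scores.mean())
    sem = float(scores.std(ddof=1) / np.sqrt(scores.size))
    tcrit = float(stats.t.ppf(0.5 + level / 2.0, scores.size - 1))
    return mean, mean - tcrit * sem, mean + tcrit * sem


@dataclass
class CohortMetrics:
    """Per-diagnosis decision counts and derived cohort metrics."""

    counts: pd.DataFrame  # index: diagnosis; columns: correct, incorrect
    sensitivity: float
    specificity: float
    group_scores: dict[str, dict] = field(default_factory=dict)


def _is_correct(diagnosis: Diagnosis, decision: Decision) -> bool:
    if diagnosis is Diagnosis.CM:
        return decision is Decision.MALIGNANT
    return decision is Decision.BENIGN


def confusion_counts(
    decisions: list[Decision], truths: list[Diagnosis]
) -> pd.DataFrame:
    """Counts of correct/incorrect decisions by diagnosis, with percentages.

    Percentages are recomputed from the counts to one decimal.
    """
    if len(decisions) != len(truths):
        raise ValueError("one decision per lesion required")
    rows = {}
    for diagnosis in Diagnosis:
        idx = [i for i, t in enumerate(truths) if Diagnosis(t) is diagnosis]
        if not idx:
            continue
        correct = sum(_is_correct(diagnosis, Decision(decisions[i])) for i in idx)
        n = len(idx)
        rows[diagnosis.value] = {
            "n": n,
            "correct": correct,
            "incorrect": n - correct,
            "pct_correct": round(100.0 * correct / n, 1),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def dominant_type(types: list[SpectralType]) -> str:
    """Most frequent informative type among a lesion's accepted spectra.

    Rejected and uninformative spectra do not compete; a tie between
    informative types (or no informative spectra at all) yields
    ``"NO_DOMINANT"``.
    """
    informative = [
        SpectralType(t) for t in types
        if SpectralType(t) not in (SpectralType.UNINFORMATIVE,
                                   SpectralType.REJECTED_LOW_SNR)
    ]
    if not informative:
        return "NO_DOMINANT"
    values, counts = np.unique([t.value for t in informative], return_counts=True)
    top = counts.max()
    winners = values[counts == top]
    if len(winners) > 1:
        return "NO_DOMINANT"
    return str(winners[0])


def spectral_type_table(
    per_lesion_types: list[list[SpectralType]], truths: list[Diagnosis]
) -> pd.DataFrame:
    """Lesions per (diagnosis, dominant spectral type): rows are diagnoses,
    columns the informative types plus a no-dominant column."""
    if len(per_lesion_types) != len(truths):
        raise ValueError("one type list per lesion required")
    columns = [SpectralType.SK_TYPE.value, SpectralType.CM_TYPE.value,
               SpectralType.NEVUS_TYPE.value, "NO_DOMINANT"]
    diagnoses = sorted({Diagnosis(t).value for t in truths})
    table = pd.DataFrame(0, index=diagnoses, columns=columns)
    for types, truth in zip(per_lesion_types, truths):
        table.loc[Diagnosis(truth).value, dominant_type(types)] += 1
    return table


def evaluate_cohort(
    scores: list[LesionScore], truths: list[Diagnosis]
) -> CohortMetrics:
    """Cohort metrics from per-lesion scores and ground-truth diagnoses."""
    if len(scores) != len(truths):
        raise ValueError("one score per lesion required")
    truths = [Diagnosis(t) for t in truths]
    decisions = [s.decision for s in scores]
    counts = confusion_counts(decisions, truths)

    cm_idx = [i for i, t in enumerate(truths) if t is Diagnosis.CM]
    benign_idx = [i for i, t in enumerate(truths) if t in _BENIGN]
    sensitivity = (
        float(np.mean([decisions[i] is Decision.MALIGNANT for i in cm_idx]))
        if cm_idx else float("nan")
    )
    specificity = (
        float(np.mean([decisions[i] is Decision.BENIGN for i in benign_idx]))
        if benign_idx else float("nan")
    )

    group_scores = {}
    for diagnosis in Diagnosis:
        vals = np.array([s.score for s, t in zip(scores, truths) if t is diagnosis])
        if vals.size == 0:
            continue
        entry = {"n": int(vals.size), "mean": float(vals.mean())}
        if vals.size >= 2:
            _, lo, hi = mean_score_ci(vals)
            entry["ci95"] = (lo, hi)
        group_scores[diagnosis.value] = entry

    return CohortMetrics(counts, sensitivity, specificity, group_scores)
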