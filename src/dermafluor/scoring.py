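"""Lesion-level score aggregation and the excision decision.

The lesion score scales linearly with the number of spectra classified as
melanoma-characteristic: it is defined here as the percentage of accepted
(classified) spectra typed malignant, a 0–100 quantity.  Spectra rejected
for low SNR leave the denominator; uninformative spectra stay in it.  A
score strictly above the cut-off (default 28) triggers the excision
recommendation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .spectra import SpectralType

__all__ = ["Decision", "LesionScore", "lesion_score", "decide", "score_from_types",
           "DEFAULT_CUTOFF"]

#: Score cut-off above which excision is recommended (strict inequality).
DEFAULT_CUTOFF = 28.0


class Decision(str, enum.Enum):
    MALIGNANT = "MALIGNANT"
    BENIGN = "BENIGN"


@dataclass(frozen=True)
class LesionScore:
    """Counts and the derived 0–100 score for one lesion."""

    lesion_id: str
    n_total: int
    n_rejected: int
    n_malignant: int
    score: float
    decision: Decision

    @property
    def n_classified(self) -> int:
        return self.n_total - self.n_rejected


def decide(score: float, cutoff: float = DEFAULT_CUTOFF) -> Decision:
    """Excision decision: malignant iff score strictly exceeds the cut-off."""
    if not 0.0 <= score <= 100.0:
        raise ValueError("score must lie in [0, 100]")
    return Decision.MALIGNANT if score > cutoff else Decision.BENIGN


def lesion_score(
    n_total: int,
    n_rejected: int,
    n_malignant: int,
    lesion_id: str = "lesion",
    cutoff: float = DEFAULT_CUTOFF,
) -> LesionScore:
    """Score = 100 * n_malignant / n_classified, with the strict cut-off.

    ``n_classified = n_total - n_rejected`` must be at least 1: a scan
    with every spectrum rejected is uninterpretable.
    """
    if n_total < 0 or n_rejected < 0 or n_malignant < 0:
        raise ValueError("counts must be nonnegative")
    n_classified = n_total - n_rejected
    if n_classified < 1:
        raise ValueError("no classified spectra; scan is uninterpretable")
    if n_malignant > n_classified:
        raise ValueError("n_malignant exceeds n_classified")
    score = 100.0 * n_malignant / n_classified
    return LesionScore(lesion_id, n_total, n_rejected, n_malignant,
                       score, decide(score, cutoff))


def score_from_types(
    types: list[SpectralType],
    n_rejected: int = 0,
    lesion_id: str = "lesion",
    cutoff: float = DEFAULT_CUTOFF,
) -> LesionScore:
    """Aggregate per-spectrum types (of accepted spectra) into a lesion score."""
    types = [SpectralType(t) for t in types]
    if any(t is SpectralType.REJECTED_LOW_SNR for t in types):
        raise ValueError("pass only accepted spectra; count rejections separately")
    n_malignant = sum(t is SpectralType.CM_TYPE for t in types)
    return lesion_score(len(types) + n_rejected, n_rejected, n_malignant,
                        lesion_id=lesion_id, cutoff=cutoff)
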