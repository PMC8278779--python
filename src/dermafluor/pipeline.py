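"""End-to-end analysis of a lesion scan: preprocess, type, score.

``analyze_scan`` is the per-lesion path the CLI stages chain together:
SNR rejection, span-40 smoothing, max normalization, feature extraction,
spectral typing, and score aggregation.  Truth metadata carried by
synthetic spectra is never consulted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import (
    FEATURE_NAMES,
    RuleBasedSpectralTyper,
    SpectralFeaturizer,
    SurrogateSpectralTyper,
)
from .preprocess import BandMaxNormalizer, MovingAverageSmoother, PreprocessConfig, \
    filter_low_snr, snr_matrix
from .scoring import DEFAULT_CUTOFF, LesionScore, score_from_types
from .spectra import LesionScan, SpectralType

__all__ = ["LesionAnalysis", "analyze_scan", "classify_scan"]


@dataclass
class LesionAnalysis:
    """Per-lesion result: score plus the per-spectrum feature/type table."""

    score: LesionScore
    table: pd.DataFrame  # spectrum_id, features, assigned_type, malignant_flag
    n_rejected: int


def classify_scan(
    scan: LesionScan,
    config: PreprocessConfig | None = None,
    typer: RuleBasedSpectralTyper | SurrogateSpectralTyper | None = None,
) -> pd.DataFrame:
    """Feature/type table for the accepted spectra of a raw scan.

    The scan must already have passed SNR filtering (rejected spectra
    removed); pass the accepted partition from
    :func:`~dermafluor.preprocess.filter_low_snr`.
    """
    config = config or PreprocessConfig()
    grid = scan.grid
    X = scan.intensity_matrix()
    snr = snr_matrix(X, grid, config)
    smoothed = MovingAverageSmoother(config.smoothing_span).fit(X).transform(X)
    normalized = BandMaxNormalizer(grid, config.normalization_band).fit(
        smoothed).transform(smoothed)
    features = SpectralFeaturizer(grid).fit(normalized).transform(normalized, snr=snr)
    if typer is None:
        typer = RuleBasedSpectralTyper().fit(features)
    types = typer.predict(features)
    table = pd.DataFrame(features, columns=list(FEATURE_NAMES))
    table.insert(0, "spectrum_id", [s.spectrum_id for s in scan.spectra])
    table["assigned_type"] = types
    table["malignant_flag"] = types == SpectralType.CM_TYPE.value
    return table


def analyze_scan(
    scan: LesionScan,
    config: PreprocessConfig | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    typer: RuleBasedSpectralTyper | SurrogateSpectralTyper | None = None,
) -> LesionAnalysis:
    """Full per-lesion analysis of a raw scan."""
    config = config or PreprocessConfig()
    accepted, rejected = filter_low_snr(scan, config)
    n_rejected = len(rejected) if rejected is not None else 0
    if accepted is None:
        raise ValueError(f"{scan.lesion_id}: every spectrum rejected; uninterpretable")
    table = classify_scan(accepted, config, typer)
    types = [SpectralType(t) for t in table["assigned_type"]]
    score = score_from_types(types, n_rejected=n_rejected,
                             lesion_id=scan.lesion_id, cutoff=cutoff)
    return LesionAnalysis(score=score, table=table, n_rejected=n_rejected)
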