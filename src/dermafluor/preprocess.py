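"""Spectrum preprocessing: moving-average smoothing, SNR rejection, normalization.

The analysis chain smooths every spectrum with a span-40 moving-average
filter, removes spectra whose signal-to-noise ratio in the 430–650 nm band
is too low for reliable classification (around 5% of acquired spectra under
the default contamination), and max-normalizes spectra where the analysis
calls for it.

The smoother, normalizer and SNR filter are exposed both as sklearn-style
transformers operating on ``(n_spectra, n_points)`` arrays and as thin
functions on :class:`~dermafluor.spectra.Spectrum` / ``LesionScan`` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .spectra import LesionScan, Spectrum, Stage, WavelengthGrid, make_default_grid

__all__ = [
    "PreprocessConfig",
    "MovingAverageSmoother",
    "BandMaxNormalizer",
    "smooth",
    "estimate_snr",
    "filter_low_snr",
    "normalize_max",
]

#: Sentinel SNR for spectra whose smoothing residual is exactly zero.
SNR_SENTINEL = np.inf


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunables of the preprocessing stage.

    ``smoothing_span`` counts grid points (40 points = 40 nm on the default
    1 nm grid); an even span is symmetrized to an odd centered window.
    ``snr_threshold`` is the acceptance cut on mean(smoothed)/sd(residual)
    within ``snr_band``.
    """

    smoothing_span: int = 40
    snr_threshold: float = 3.0
    snr_band: tuple[float, float] = (430.0, 650.0)
    normalization_band: tuple[float, float] = (380.0, 680.0)

    def __post_init__(self) -> None:
        if self.smoothing_span < 1:
            raise ValueError("smoothing_span must be >= 1")
        if self.snr_threshold <= 0:
            raise ValueError("snr_threshold must be positive")


def _moving_average(matrix: np.ndarray, span: int) -> np.ndarray:
    """Centered moving average along the last axis.

    An even ``span`` is symmetrized to the odd window ``span + 1`` so the
    filter stays centered.  At the edges the window shrinks symmetrically to
    the largest centered window that fits.
    """
    x = np.atleast_2d(np.asarray(matrix, dtype=float))
    n = x.shape[-1]
    if not 1 <= span <= n:
        raise ValueError(f"span {span} out of range [1, {n}]")
    half = span // 2
    if half == 0:  # window of one point: exact identity
        return np.array(matrix, dtype=float)
    # cumulative sum with a leading zero: window sums by subtraction
    cs = np.concatenate([np.zeros(x.shape[:-1] + (1,)), np.cumsum(x, axis=-1)], axis=-1)
    idx = np.arange(n)
    k = np.minimum(half, np.minimum(idx, n - 1 - idx))  # per-point half-width
    lo, hi = idx - k, idx + k
    out = (cs[..., hi + 1] - cs[..., lo]) / (2 * k + 1)
    return out.reshape(np.shape(matrix))


class MovingAverageSmoother(TransformerMixin, BaseEstimator):
    """Centered moving-average filter over the wavelength axis.

    Parameters
    ----------
    span : int, default 40
        Window length in grid points.  Even spans are symmetrized to the
        next odd window (span 40 -> effective 41-point window) so the
        filter is centered; edge windows shrink symmetrically.
    """

    def __init__(self, span: int = 40):
        self.span = span

    def fit(self, X, y=None):
        X = check_array(X)
        if not 1 <= self.span <= X.shape[1]:
            raise ValueError(f"span {self.span} out of range [1, {X.shape[1]}]")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return _moving_average(X, self.span)


class BandMaxNormalizer(TransformerMixin, BaseEstimator):
    """Scale each spectrum so its maximum within a wavelength band is 1.

    Parameters
    ----------
    grid : WavelengthGrid, optional
        Grid the columns of X live on (default: the 380–680 nm grid).
    band : (float, float), default (380, 680)
        Closed wavelength interval the maximum is taken over, nm.
    """

    def __init__(self, grid: WavelengthGrid | None = None,
                 band: tuple[float, float] = (380.0, 680.0)):
        self.grid = grid
        self.band = band

    def fit(self, X, y=None):
        X = check_array(X)
        grid = self.grid or make_default_grid()
        if X.shape[1] != grid.n_points:
            raise ValueError("X columns do not match the wavelength grid")
        self.grid_ = grid
        self.band_slice_ = grid.band_slice(*self.band)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        peak = X[:, self.band_slice_].max(axis=1)
        if np.any(peak <= 0):
            raise ValueError("nonpositive band maximum; cannot normalize")
        return X / peak[:, None]


# ---------------------------------------------------------------------------
# Spectrum / LesionScan wrappers
# ---------------------------------------------------------------------------

def smooth(spectrum: Spectrum, span: int = 40) -> Spectrum:
    """Smooth a raw spectrum with the centered moving-average filter."""
    if spectrum.stage is not Stage.RAW:
        raise ValueError(f"smooth expects a raw spectrum, got {spectrum.stage.value}")
    values = _moving_average(spectrum.intensities, span)
    return spectrum.with_intensities(values, Stage.SMOOTHED)


def estimate_snr(spectrum: Spectrum, config: PreprocessConfig | None = None) -> float:
    """Signal-to-noise ratio: mean(smoothed) / sd(raw - smoothed) in the SNR band.

    Returns 0 for an all-zero spectrum and ``inf`` when the smoothing
    residual vanishes while signal is present (noise-free input).
    """
    config = config or PreprocessConfig()
    if spectrum.stage is not Stage.RAW:
        raise ValueError("estimate_snr expects a raw spectrum")
    band = spectrum.grid.band_slice(*config.snr_band)
    raw = spectrum.intensities[band]
    smoothed = _moving_average(spectrum.intensities, config.smoothing_span)[band]
    signal = float(smoothed.mean())
    noise = float(np.std(raw - smoothed))
    if noise == 0.0:
        return SNR_SENTINEL if signal > 0 else 0.0
    return signal / noise


def snr_matrix(X: np.ndarray, grid: WavelengthGrid,
               config: PreprocessConfig | None = None) -> np.ndarray:
    """Vectorized :func:`estimate_snr` over the rows of X."""
    config = config or PreprocessConfig()
    band = grid.band_slice(*config.snr_band)
    X = np.asarray(X, dtype=float)
    smoothed = _moving_average(X, config.smoothing_span)
    signal = smoothed[:, band].mean(axis=1)
    noise = np.std(X[:, band] - smoothed[:, band], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(noise == 0.0, np.where(signal > 0, np.inf, 0.0), signal / noise)
    return snr


def filter_low_snr(
    scan: LesionScan, config: PreprocessConfig | None = None
) -> tuple[LesionScan | None, LesionScan | None]:
    """Partition a raw scan into (accepted, rejected) by the SNR threshold.

    Order is preserved; either part may be ``None`` when empty (a
    ``LesionScan`` cannot be empty).
    """
    config = config or PreprocessConfig()
    snrs = snr_matrix(scan.intensity_matrix(), scan.grid, config)
    accepted, rejected = [], []
    for s, snr in zip(scan.spectra, snrs):
        target = accepted if snr >= config.snr_threshold else rejected
        s = s.copy()
        s.meta["snr"] = float(snr)
        target.append(s)

    def _part(spectra: list[Spectrum]) -> LesionScan | None:
        if not spectra:
            return None
        return LesionScan(scan.lesion_id, spectra, diagnosis=scan.diagnosis,
                          meta=dict(scan.meta))

    return _part(accepted), _part(rejected)


def normalize_max(
    spectrum: Spectrum, band: tuple[float, float] = (380.0, 680.0)
) -> Spectrum:
    """Divide by the band maximum so the spectrum peaks at exactly 1."""
    sl = spectrum.grid.band_slice(*band)
    peak = float(spectrum.intensities[sl].max())
    if peak <= 0:
        raise ValueError("nonpositive band maximum; cannot normalize")
    return spectrum.with_intensities(spectrum.intensities / peak, Stage.NORMALIZED)
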