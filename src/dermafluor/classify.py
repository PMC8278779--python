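"""Per-spectrum feature extraction and spectral-type assignment.

Every accepted spectrum is reduced to six features computed on its
smoothed, max-normalized form:

* ``shg_band`` — mean intensity over 395–405 nm (collagen second-harmonic),
* ``blue_band`` — mean over 450–490 nm (NAD(P)H + keratin),
* ``red_band`` — mean over 550–650 nm (melanin),
* ``monotonicity`` — Spearman rank correlation of intensity with wavelength
  over 430–650 nm (the melanoma signature is a monotone rise),
* ``peak_nm`` — argmax wavelength over 430–520 nm,
* ``snr`` — carried over from preprocessing.

Two interchangeable backends assign the spectral type: a transparent
rule-based classifier (the primary backend) and a trainable linear
margin classifier standing in for the certified device's SVM, whose
weights are not public.  The surrogate is a stand-in, not a reproduction
of the device.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .preprocess import PreprocessConfig, _moving_average
from .spectra import SpectralType, Spectrum, Stage, WavelengthGrid, make_default_grid

__all__ = [
    "SpectrumFeatures",
    "TypingThresholds",
    "FEATURE_NAMES",
    "SpectralFeaturizer",
    "extract_features",
    "RuleBasedSpectralTyper",
    "SurrogateSpectralTyper",
    "classify_rule",
    "is_malignant_type",
    "train_surrogate",
]

SHG_BAND = (395.0, 405.0)
BLUE_BAND = (450.0, 490.0)
RED_BAND = (550.0, 650.0)
MONOTONICITY_BAND = (430.0, 650.0)
PEAK_BAND = (430.0, 520.0)

FEATURE_NAMES = ("shg_band", "blue_band", "red_band", "monotonicity", "peak_nm", "snr")


@dataclass(frozen=True)
class SpectrumFeatures:
    """The six per-spectrum features (see module docstring)."""

    shg_band: float
    blue_band: float
    red_band: float
    monotonicity: float
    peak_nm: float
    snr: float = np.inf

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES])


@dataclass(frozen=True)
class TypingThresholds:
    """Cuts of the rule-based typer (calibrated on the noise-free templates).

    ``shg_high``: minimum normalized 395–405 nm mean for a nevus-dominant
    second-harmonic line; ``shg_low``: maximum for a suppressed line;
    ``blue_dominance``: minimum blue/red band ratio for the SK rule;
    ``monotonicity_min``: minimum Spearman correlation for the melanoma rule.
    """

    shg_high: float = 0.7
    shg_low: float = 0.4
    blue_dominance: float = 2.0
    monotonicity_min: float = 0.95

    def __post_init__(self) -> None:
        if min(self.shg_high, self.shg_low, self.blue_dominance,
               self.monotonicity_min) <= 0:
            raise ValueError("thresholds must be positive")
        if self.shg_low >= self.shg_high:
            raise ValueError("shg_low must be below shg_high")


def _spearman_rows(Y: np.ndarray) -> np.ndarray:
    """Spearman correlation of each row of Y against the column index."""
    ranks = rankdata(Y, axis=-1)
    n = Y.shape[-1]
    x = np.arange(1, n + 1, dtype=float)
    xc = x - x.mean()
    rc = ranks - ranks.mean(axis=-1, keepdims=True)
    denom = np.sqrt((rc**2).sum(axis=-1) * (xc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (rc * xc).sum(axis=-1) / denom, 0.0)
    return rho


class SpectralFeaturizer(BaseEstimator):
    """Transform smoothed+normalized spectra into the 6-column feature matrix.

    Input rows must already be smoothed and band-max normalized; the SNR
    column is filled from ``snr`` passed to :meth:`transform` (it is a
    property of the raw spectrum) or with ``inf`` when absent.
    """

    def __init__(self, grid: WavelengthGrid | None = None):
        self.grid = grid

    def fit(self, X, y=None):
        X = check_array(X)
        grid = self.grid or make_default_grid()
        if X.shape[1] != grid.n_points:
            raise ValueError("X columns do not match the wavelength grid")
        self.grid_ = grid
        self._bands = {
            "shg": grid.band_slice(*SHG_BAND),
            "blue": grid.band_slice(*BLUE_BAND),
            "red": grid.band_slice(*RED_BAND),
            "mono": grid.band_slice(*MONOTONICITY_BAND),
            "peak": grid.band_slice(*PEAK_BAND),
        }
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, snr: np.ndarray | None = None):
        check_is_fitted(self)
        X = check_array(X)
        b = self._bands
        wl = self.grid_.wavelengths
        shg = X[:, b["shg"]].mean(axis=1)
        blue = X[:, b["blue"]].mean(axis=1)
        red = X[:, b["red"]].mean(axis=1)
        mono = _spearman_rows(X[:, b["mono"]])
        peak = wl[b["peak"]][np.argmax(X[:, b["peak"]], axis=1)]
        if snr is None:
            snr = np.full(X.shape[0], np.inf)
        return np.column_stack([shg, blue, red, mono, peak, snr])

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X).transform(X, **kwargs)


def extract_features(
    spectrum: Spectrum, snr: float = np.inf, grid: WavelengthGrid | None = None
) -> SpectrumFeatures:
    """Features of one smoothed+normalized spectrum."""
    if spectrum.stage is not Stage.NORMALIZED:
        raise ValueError(
            f"extract_features expects a normalized spectrum, got {spectrum.stage.value}"
        )
    feat = SpectralFeaturizer(grid or spectrum.grid).fit_transform(
        spectrum.intensities[None, :], snr=np.array([snr])
    )[0]
    return SpectrumFeatures(*feat)


def classify_rule(
    features: SpectrumFeatures, thresholds: TypingThresholds | None = None
) -> SpectralType:
    """Assign a spectral type by the first matching rule.

    Order (first match wins): nevus (dominant second-harmonic line), SK
    (suppressed line, blue-dominant, peak in 450–490 nm), melanoma
    (suppressed line, monotone rise over 430–650 nm), else uninformative.
    """
    t = thresholds or TypingThresholds()
    X = features.as_array()[None, :]
    typer = RuleBasedSpectralTyper(t).fit(X)
    return SpectralType(typer.predict(X)[0])


class RuleBasedSpectralTyper(ClassifierMixin, BaseEstimator):
    """Transparent rule-based spectral typer on the 6-column feature matrix.

    A total function: every row receives exactly one of the four
    informative types; the decision depends only on normalized features,
    so it is invariant to rescaling the underlying spectrum.
    """

    def __init__(self, thresholds: TypingThresholds | None = None):
        self.thresholds = thresholds

    def fit(self, X, y=None):
        X = check_array(X, ensure_all_finite=False)  # snr column may be inf
        if X.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"expected {len(FEATURE_NAMES)} feature columns")
        self.thresholds_ = self.thresholds or TypingThresholds()
        self.classes_ = np.array(
            [SpectralType.CM_TYPE.value, SpectralType.NEVUS_TYPE.value,
             SpectralType.SK_TYPE.value, SpectralType.UNINFORMATIVE.value]
        )
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X, ensure_all_finite=False)  # snr column may be inf
        t = self.thresholds_
        shg, blue, red, mono, peak = (X[:, i] for i in range(5))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(red > 0, blue / red, np.inf)
        out = np.full(X.shape[0], SpectralType.UNINFORMATIVE.value, dtype=object)
        # the nevus signature is a *dominant* second-harmonic line, so the
        # 400 nm band must also exceed the blue band (a flat spectrum has a
        # high 400 nm level but no line and stays uninformative)
        nevus = (shg >= t.shg_high) & (ratio < t.blue_dominance) & (shg > blue)
        sk = (~nevus & (shg <= t.shg_low) & (ratio >= t.blue_dominance)
              & (peak >= 450.0) & (peak <= 490.0))
        cm = ~nevus & ~sk & (mono >= t.monotonicity_min) & (shg <= t.shg_low)
        out[nevus] = SpectralType.NEVUS_TYPE.value
        out[sk] = SpectralType.SK_TYPE.value
        out[cm] = SpectralType.CM_TYPE.value
        return out.astype(str)


def is_malignant_type(spectral_type: SpectralType) -> bool:
    """True iff the type is the melanoma-characteristic one."""
    spectral_type = SpectralType(spectral_type)
    if spectral_type is SpectralType.REJECTED_LOW_SNR:
        raise ValueError("rejected spectra carry no malignancy evidence")
    return spectral_type is SpectralType.CM_TYPE


class SurrogateSpectralTyper(ClassifierMixin, BaseEstimator):
    """Linear margin classifier on spectrum features (SVM stand-in).

    A StandardScaler + LinearSVC pipeline trained on generator truth
    labels.  It stands in for the certified device's SVM, whose feature
    set and weights are proprietary; it is never a reproduction of the
    device's decisions.
    """

    def __init__(self, C: float = 1.0, random_state: int = 0,
                 min_per_class: int = 50):
        self.C = C
        self.random_state = random_state
        self.min_per_class = min_per_class

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float, ensure_all_finite=False)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need at least two classes")
        if counts.min() < self.min_per_class:
            lacking = classes[counts < self.min_per_class]
            raise ValueError(
                f"need >= {self.min_per_class} spectra per class; short: {lacking}"
            )
        self.model_ = make_pipeline(
            StandardScaler(),
            LinearSVC(C=self.C, random_state=self.random_state, max_iter=20000),
        )
        # drop the snr column: it reflects acquisition quality, not type
        self.model_.fit(X[:, :5], y)
        self.classes_ = self.model_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X, ensure_all_finite=False)
        return self.model_.predict(X[:, :5])


def train_surrogate(
    features: np.ndarray, labels: np.ndarray, seed: int = 0
) -> SurrogateSpectralTyper:
    """Fit the surrogate typer on labeled feature rows (generator truth)."""
    return SurrogateSpectralTyper(random_state=seed).fit(features, labels)
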