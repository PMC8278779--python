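"""Nonnegative spectral unmixing and the difference-spectrum procedure.

Smoothed spectra are decomposed onto the fluorophore bases by nonnegative
least squares, the quantitative counterpart of reading composite spectra
as overlapping SHG, NAD(P)H, keratin and melanin contributions.  The
difference-spectrum procedure isolates what a target spectrum contains
beyond a reference: the reference is rescaled to the target's maximum and
subtracted (applied to seborrheic keratosis minus hyperkeratotic skin, it
exposes the NAD(P)H excess at 430–460 nm and the melanin excess beyond
530 nm).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .fluorophores import FluorophoreBasis, default_basis_set
from .preprocess import _moving_average
from .spectra import Spectrum, Stage, WavelengthGrid, make_default_grid

__all__ = [
    "NNLSUnmixer",
    "nnls_unmix",
    "difference_spectrum",
    "peak_wavelength",
]


class NNLSUnmixer(TransformerMixin, BaseEstimator):
    """Nonnegative least-squares decomposition onto fluorophore bases.

    ``transform`` maps ``(n_spectra, n_points)`` intensity rows to
    ``(n_spectra, n_bases)`` weights minimizing
    ``||x - sum_b w_b basis_b||_2`` subject to ``w_b >= 0``.
    Fitted attributes: ``components_`` (basis matrix), ``basis_names_``,
    ``residual_norm_`` (per-row residuals of the last transform).
    """

    def __init__(self, basis_set: dict[str, FluorophoreBasis] | None = None,
                 grid: WavelengthGrid | None = None):
        self.basis_set = basis_set
        self.grid = grid

    def fit(self, X=None, y=None):
        grid = self.grid or make_default_grid()
        basis_set = self.basis_set if self.basis_set is not None else default_basis_set(grid)
        for name, basis in basis_set.items():
            if basis.grid != grid:
                raise ValueError(f"basis {name} is on a different grid")
        if len(basis_set) >= grid.n_points:
            raise ValueError("need fewer bases than grid points")
        self.grid_ = grid
        self.basis_names_ = list(basis_set)
        self.components_ = np.vstack([basis_set[n].values for n in self.basis_names_])
        self.n_features_in_ = grid.n_points
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        if X.shape[1] != self.components_.shape[1]:
            raise ValueError("X columns do not match the basis grid")
        A = self.components_.T
        weights = np.empty((X.shape[0], A.shape[1]))
        residuals = np.empty(X.shape[0])
        for i, row in enumerate(X):
            weights[i], residuals[i] = nnls(A, row)
        self.residual_norm_ = residuals
        return weights

    def inverse_transform(self, W):
        check_is_fitted(self)
        W = check_array(W)
        return W @ self.components_


def nnls_unmix(
    spectrum: Spectrum,
    basis_set: dict[str, FluorophoreBasis] | None = None,
) -> tuple[dict[str, float], float]:
    """Unmix one smoothed spectrum; returns (weights by basis name, residual norm).

    Operates on smoothed, unnormalized intensities so the weights keep the
    detector-counts scale.
    """
    unmixer = NNLSUnmixer(basis_set, spectrum.grid).fit()
    W = unmixer.transform(spectrum.intensities[None, :])
    weights = dict(zip(unmixer.basis_names_, (float(w) for w in W[0])))
    return weights, float(unmixer.residual_norm_[0])


def difference_spectrum(target: Spectrum, reference: Spectrum,
                        span: int = 40) -> Spectrum:
    """Target minus the reference rescaled to the target's maximum.

    Raw inputs are smoothed first (already-smoothed inputs pass through);
    the reference is scaled so its full-range maximum equals the target's,
    then subtracted.  The result may be negative and is tagged with the
    difference stage.
    """
    if target.grid != reference.grid:
        raise ValueError("target and reference must share a grid")

    def _smoothed(s: Spectrum) -> np.ndarray:
        if s.stage is Stage.RAW:
            return _moving_average(s.intensities, span)
        return np.asarray(s.intensities, dtype=float)

    t = _smoothed(target)
    r = _smoothed(reference)
    t_max = float(t.max())
    if t_max <= 0:
        raise ValueError("target maximum must be positive")
    r_max = float(r.max())
    if r_max <= 0:
        raise ValueError("reference maximum must be positive")
    diff = t - r * (t_max / r_max)
    return Spectrum(target.grid, diff, spectrum_id=f"{target.spectrum_id}-diff",
                    stage=Stage.DIFFERENCE, meta={"reference": reference.spectrum_id})


def peak_wavelength(spectrum: Spectrum | FluorophoreBasis,
                    band: tuple[float, float]) -> float:
    """Wavelength of the maximum within a closed band; ties break toward
    the shorter wavelength (argmax returns the first maximum)."""
    grid = spectrum.grid
    values = spectrum.values if isinstance(spectrum, FluorophoreBasis) else spectrum.intensities
    sl = grid.band_slice(*band)
    segment = np.asarray(values[sl], dtype=float)
    if np.all(segment == 0):
        raise ValueError("spectrum is identically zero within the band")
    return float(grid.wavelengths[sl][int(np.argmax(segment))])
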