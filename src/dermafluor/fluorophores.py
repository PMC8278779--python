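"""Fluorophore basis shapes and the forward model for skin phenotypes.

Two-photon-excited skin fluorescence in the 380–680 nm window is modelled
as a nonnegative linear combination of four components:

* **SHG** — the second harmonic of the 800 nm excitation, a narrow line at
  400 nm generated by microcrystalline dermal collagen,
* **NADH** — NAD(P)H coenzyme fluorescence, a broad band peaking at 450 nm,
* **KERATIN** — keratin fluorescence peaking at 470 nm,
* **MELANIN** — eumelanin/pheomelanin fluorescence rising monotonically
  toward long wavelengths and dominating the signal above ~550 nm.

Gaussian lines and a sigmoidal rising tail are the simplest shapes
satisfying every constraint the phenotypes impose (peak positions,
monotonicity over 430–650 nm, band dominance); no published emission
lineshapes exist for this instrument.  Phenotype templates (seborrheic
keratosis, melanoma, nevus, and the reference measurements) are fixed
weighted mixtures of these bases.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .spectra import Spectrum, Stage, WavelengthGrid, make_default_grid

__all__ = [
    "FluorophoreBasis",
    "BasisShape",
    "Phenotype",
    "PhenotypeTemplate",
    "basis_shg",
    "basis_gaussian",
    "basis_melanin",
    "default_basis_set",
    "compose",
    "compose_template",
    "DEFAULT_TEMPLATE_WEIGHTS",
    "DEFAULT_TEMPLATE_SCALES",
]

#: Default Gaussian sigma of the SHG line, nm.
SHG_LINEWIDTH_NM = 5.0
#: Default NADH band: peak and full width at half maximum, nm.
NADH_PEAK_NM, NADH_FWHM_NM = 450.0, 60.0
#: Default keratin band: peak and FWHM, nm.  The width is a free design
#: parameter fixed by the template calibration (see docs/methods.md).
KERATIN_PEAK_NM, KERATIN_FWHM_NM = 470.0, 80.0
#: Default melanin tail: sigmoid midpoint ("onset") and softness, nm.
#: A steep onset near the blue-green region gives the tail enough local
#: slope at 475 nm to shift the SK composite peak red-ward without
#: swamping the 550-650 nm band (calibration, see docs/methods.md).
MELANIN_ONSET_NM, MELANIN_SOFTNESS_NM = 470.0, 15.0
#: Linear ramp mixed into the melanin tail so it keeps rising to the red
#: edge instead of saturating (melanin emission has no plateau in-band).
MELANIN_RAMP = 0.15

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class BasisShape(str, enum.Enum):
    GAUSSIAN_LINE = "gaussian_line"
    RISING_TAIL = "rising_tail"


class Phenotype(str, enum.Enum):
    """Spectral phenotypes: the three lesion types plus reference measurements."""

    SK = "SK"
    CM = "CM"
    NEVUS = "NEVUS"
    HYPERKERATOTIC = "HYPERKERATOTIC"
    HEALTHY_FOREARM = "HEALTHY_FOREARM"
    PURE_KERATIN = "PURE_KERATIN"
    PURE_NADH = "PURE_NADH"
    BACKGROUND = "BACKGROUND"  # uninformative broad autofluorescence


@dataclass(frozen=True)
class FluorophoreBasis:
    """A unit-max component emission shape evaluated on a grid."""

    name: str
    shape: BasisShape
    peak_nm: float
    width_nm: float
    grid: WavelengthGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (self.grid.n_points,):
            raise ValueError("basis values do not match grid")
        if np.any(v < 0):
            raise ValueError("basis values must be nonnegative")


def basis_shg(
    excitation_nm: float = 800.0,
    linewidth_nm: float = SHG_LINEWIDTH_NM,
    grid: WavelengthGrid | None = None,
) -> FluorophoreBasis:
    """Second-harmonic line: a Gaussian at half the excitation wavelength.

    ``linewidth_nm`` is the Gaussian sigma.  Frequency doubling of the
    800 nm excitation places the line at 400 nm.
    """
    grid = grid or make_default_grid()
    if linewidth_nm <= 0:
        raise ValueError("linewidth_nm must be positive")
    center = excitation_nm / 2.0
    if not grid.covers(center):
        raise ValueError(
            f"SHG center {center} nm lies outside the grid "
            f"[{grid.start_nm}, {grid.stop_nm}] nm"
        )
    wl = grid.wavelengths
    values = np.exp(-0.5 * ((wl - center) / linewidth_nm) ** 2)
    values /= values.max()
    return FluorophoreBasis("SHG", BasisShape.GAUSSIAN_LINE, center, linewidth_nm, grid, values)


def basis_gaussian(
    name: str,
    peak_nm: float,
    fwhm_nm: float,
    grid: WavelengthGrid | None = None,
) -> FluorophoreBasis:
    """Unit-max Gaussian emission band parameterized by peak and FWHM."""
    grid = grid or make_default_grid()
    if fwhm_nm <= 0:
        raise ValueError("fwhm_nm must be positive")
    if not grid.covers(peak_nm):
        raise ValueError(f"peak {peak_nm} nm is off-grid")
    sigma = fwhm_nm * _FWHM_TO_SIGMA
    wl = grid.wavelengths
    values = np.exp(-0.5 * ((wl - peak_nm) / sigma) ** 2)
    values /= values.max()
    return FluorophoreBasis(name, BasisShape.GAUSSIAN_LINE, peak_nm, fwhm_nm, grid, values)


def basis_melanin(
    onset_nm: float = MELANIN_ONSET_NM,
    softness_nm: float = MELANIN_SOFTNESS_NM,
    ramp: float = MELANIN_RAMP,
    grid: WavelengthGrid | None = None,
) -> FluorophoreBasis:
    """Melanin tail: a sigmoid plus gentle linear ramp, rising monotonically.

    ``onset_nm`` is the sigmoid midpoint, ``softness_nm`` the 1/e width;
    ``ramp`` is the relative weight of a linear rise across the grid,
    keeping the tail strictly increasing up to the red edge (melanin
    emission does not plateau within the acquisition band).  Normalized so
    the value at the grid maximum wavelength (680 nm by default) is 1.
    """
    grid = grid or make_default_grid()
    if not (grid.start_nm <= onset_nm <= grid.stop_nm):
        raise ValueError("onset_nm must lie within the grid")
    if softness_nm <= 0:
        raise ValueError("softness_nm must be positive")
    if ramp < 0:
        raise ValueError("ramp must be nonnegative")
    wl = grid.wavelengths
    values = 1.0 / (1.0 + np.exp(-(wl - onset_nm) / softness_nm))
    values = values + ramp * (wl - grid.start_nm) / (grid.stop_nm - grid.start_nm)
    values /= values[-1]
    return FluorophoreBasis(
        "MELANIN", BasisShape.RISING_TAIL, grid.stop_nm, softness_nm, grid, values
    )


def default_basis_set(grid: WavelengthGrid | None = None) -> dict[str, FluorophoreBasis]:
    """The four default bases keyed by name, on the given grid."""
    grid = grid or make_default_grid()
    return {
        "SHG": basis_shg(grid=grid),
        "NADH": basis_gaussian("NADH", NADH_PEAK_NM, NADH_FWHM_NM, grid=grid),
        "KERATIN": basis_gaussian("KERATIN", KERATIN_PEAK_NM, KERATIN_FWHM_NM, grid=grid),
        "MELANIN": basis_melanin(grid=grid),
    }


def compose(
    weights: dict[str, float],
    basis_set: dict[str, FluorophoreBasis] | None = None,
    grid: WavelengthGrid | None = None,
    spectrum_id: str = "composite",
) -> Spectrum:
    """Linear forward model: intensities = sum of weight_b * basis_b."""
    grid = grid or make_default_grid()
    basis_set = basis_set if basis_set is not None else default_basis_set(grid)
    total = np.zeros(grid.n_points)
    for name, w in weights.items():
        if w < 0:
            raise ValueError(f"negative weight for {name}")
        basis = basis_set[name]
        if basis.grid != grid:
            raise ValueError(f"basis {name} is on a different grid")
        total += w * basis.values
    return Spectrum(grid, total, spectrum_id=spectrum_id, stage=Stage.RAW)


# ---------------------------------------------------------------------------
# Phenotype templates.
#
# Weights are fixed constants calibrated once (see docs/methods.md):
# the SK melanin weight was found by a 1-D bisection so that the composite
# argmax over 430-520 nm equals 475 nm on both the raw template and its
# span-40 smoothed version (keratin peaks at 470 nm; the rising melanin tail
# drags the composite maximum red-ward).  The SK overall scale sets the
# SK blue-band (450-490 nm) mean to 10x the nevus blue-band mean.
# ---------------------------------------------------------------------------

#: Calibrated SK melanin weight: the fixed result of the documented 1-D
#: search performed by :func:`calibrate_sk_melanin_weight`.
SK_MELANIN_WEIGHT = 0.60

#: Per-phenotype mixture weights over the default bases (counts scale,
#: relative within each template before overall_scale is applied).
#: The hyperkeratotic template carries almost no NADH: terminally
#: differentiated corneocytes lack metabolizing cells, so its blue-green
#: signal is essentially pure keratin plus pigment.
DEFAULT_TEMPLATE_WEIGHTS: dict[Phenotype, dict[str, float]] = {
    Phenotype.SK: {"SHG": 0.15, "NADH": 0.20, "KERATIN": 1.0,
                   "MELANIN": SK_MELANIN_WEIGHT},
    Phenotype.CM: {"SHG": 0.05, "NADH": 0.02, "KERATIN": 0.02, "MELANIN": 1.0},
    Phenotype.NEVUS: {"SHG": 1.0, "NADH": 0.06, "KERATIN": 0.06, "MELANIN": 0.08},
    Phenotype.HYPERKERATOTIC: {"SHG": 0.05, "NADH": 0.02, "KERATIN": 1.0,
                               "MELANIN": 0.45},
    Phenotype.HEALTHY_FOREARM: {"SHG": 1.0, "NADH": 0.05, "KERATIN": 0.05,
                                "MELANIN": 0.03},
    Phenotype.PURE_KERATIN: {"KERATIN": 1.0},
    Phenotype.PURE_NADH: {"NADH": 1.0},
}

#: Overall intensity scale per phenotype, relative to the nevus template.
#: The SK scale is calibrated so the SK blue-band (450-490 nm) mean is
#: exactly 10x the nevus blue-band mean (the upper end of the observed
#: intensity contrast between SK and nevi/melanoma).
SK_OVERALL_SCALE = 0.9995
DEFAULT_TEMPLATE_SCALES: dict[Phenotype, float] = {
    Phenotype.SK: SK_OVERALL_SCALE,
    Phenotype.CM: 1.0,
    Phenotype.NEVUS: 1.0,
    Phenotype.HYPERKERATOTIC: 1.0,
    Phenotype.HEALTHY_FOREARM: 1.0,
    Phenotype.PURE_KERATIN: 1.0,
    Phenotype.PURE_NADH: 1.0,
    Phenotype.BACKGROUND: 0.5,
}


def calibrate_sk_melanin_weight(
    grid: WavelengthGrid | None = None,
    step: float = 0.01,
    max_weight: float = 1.2,
) -> float:
    """The documented 1-D search fixing the SK melanin weight.

    With the other SK weights held at their defaults, scan the melanin
    weight upward until the composite argmax over 430-520 nm equals 475 nm
    on both the raw template and its span-40 smoothed version (the keratin
    basis peaks at 470 nm; the rising melanin tail drags the composite
    maximum red-ward).  Returns the first weight satisfying both; its
    result is frozen as :data:`SK_MELANIN_WEIGHT`.
    """
    from .preprocess import _moving_average

    grid = grid or make_default_grid()
    wl = grid.wavelengths
    sl = grid.band_slice(430.0, 520.0)
    base = dict(DEFAULT_TEMPLATE_WEIGHTS[Phenotype.SK])
    bases = default_basis_set(grid)
    n_steps = int(round(max_weight / step))
    for i in range(n_steps + 1):
        w = i * step
        base["MELANIN"] = w
        v = compose(base, bases, grid).intensities
        if wl[sl][np.argmax(v[sl])] != 475.0:
            continue
        smoothed = _moving_average(v, 40)
        if wl[sl][np.argmax(smoothed[sl])] == 475.0:
            return round(w, 10)
    raise RuntimeError("no melanin weight places the SK composite peak at 475 nm")


@dataclass(frozen=True)
class PhenotypeTemplate:
    """A noise-free phenotype spectrum: weights, scale, and identity."""

    phenotype: Phenotype
    weights: dict[str, float]
    overall_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.overall_scale <= 0:
            raise ValueError("overall_scale must be positive")
        if not self.weights or all(w == 0 for w in self.weights.values()):
            raise ValueError("template needs at least one positive weight")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("template weights must be nonnegative")


def _background_values(grid: WavelengthGrid) -> np.ndarray:
    """Broad featureless autofluorescence hump (uninformative spectra)."""
    wl = grid.wavelengths
    sigma = 200.0 * _FWHM_TO_SIGMA
    v = np.exp(-0.5 * ((wl - 500.0) / sigma) ** 2)
    return v / v.max()


def get_template(phenotype: Phenotype | str) -> PhenotypeTemplate:
    """The default template (weights + scale) for a phenotype."""
    phenotype = Phenotype(phenotype)
    if phenotype is Phenotype.BACKGROUND:
        return PhenotypeTemplate(
            phenotype, {"BACKGROUND": 1.0}, DEFAULT_TEMPLATE_SCALES[phenotype]
        )
    weights = dict(DEFAULT_TEMPLATE_WEIGHTS[phenotype])
    return PhenotypeTemplate(phenotype, weights, DEFAULT_TEMPLATE_SCALES[phenotype])


def compose_template(
    phenotype: Phenotype | str,
    grid: WavelengthGrid | None = None,
    weights: dict[str, float] | None = None,
    overall_scale: float | None = None,
    basis_set: dict[str, FluorophoreBasis] | None = None,
) -> Spectrum:
    """Noise-free template spectrum of a phenotype on the given grid.

    ``weights`` / ``overall_scale`` override the calibrated defaults (used
    by config-driven pipelines); the background template has a fixed broad
    shape and honors only the scale.
    """
    grid = grid or make_default_grid()
    phenotype = Phenotype(phenotype)
    template = get_template(phenotype)
    scale = overall_scale if overall_scale is not None else template.overall_scale
    if scale <= 0:
        raise ValueError("overall_scale must be positive")
    if phenotype is Phenotype.BACKGROUND:
        values = scale * _background_values(grid)
        return Spectrum(
            grid, values, spectrum_id="template_BACKGROUND", stage=Stage.RAW,
            meta={"phenotype": phenotype.value},
        )
    spec = compose(weights if weights is not None else template.weights,
                   basis_set=basis_set, grid=grid,
                   spectrum_id=f"template_{phenotype.value}")
    spec.intensities *= scale
    spec.meta["phenotype"] = phenotype.value
    return spec
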