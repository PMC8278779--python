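"""Core spectral data types and the on-disk spectra format.

A dermatofluoroscopy scan of a pigmented skin lesion (PSL) yields a
collection of emission spectra, each an intensity-versus-wavelength trace
over the acquisition range 380–680 nm.  This module defines the wavelength
grid, the single-spectrum container, the per-lesion scan container, and a
plain-text tab-separated reader/writer used by every pipeline stage.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "LesionScan",
    "Stage",
    "Diagnosis",
    "SpectralType",
    "SpectraFormatError",
    "make_default_grid",
    "read_scan",
    "write_scan",
]

#: Acquisition range of the instrument, nm.
DEFAULT_START_NM = 380.0
DEFAULT_STOP_NM = 680.0
DEFAULT_STEP_NM = 1.0


class Stage(str, enum.Enum):
    """Processing stage of a spectrum."""

    RAW = "raw"
    SMOOTHED = "smoothed"
    NORMALIZED = "normalized"
    DIFFERENCE = "difference"


class Diagnosis(str, enum.Enum):
    """Histopathological ground-truth label of a lesion."""

    SK = "SK"              # seborrheic keratosis (benign)
    NEVUS = "NEVUS"        # melanocytic nevus (benign)
    CM = "CM"              # cutaneous melanoma (malignant)
    UNKNOWN = "UNKNOWN"


class SpectralType(str, enum.Enum):
    """Per-spectrum label assigned by the classification stage."""

    SK_TYPE = "SK_TYPE"
    CM_TYPE = "CM_TYPE"
    NEVUS_TYPE = "NEVUS_TYPE"
    UNINFORMATIVE = "UNINFORMATIVE"
    REJECTED_LOW_SNR = "REJECTED_LOW_SNR"


class SpectraFormatError(ValueError):
    """Raised when a spectra file violates the on-disk format contract."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid in nanometres.

    Invariant: ``n_points == (stop_nm - start_nm) / step_nm + 1`` exactly.
    """

    start_nm: float
    stop_nm: float
    step_nm: float
    n_points: int

    def __post_init__(self) -> None:
        if not self.start_nm < self.stop_nm:
            raise ValueError("start_nm must be < stop_nm")
        if self.step_nm <= 0:
            raise ValueError("step_nm must be positive")
        expected = (self.stop_nm - self.start_nm) / self.step_nm + 1
        if abs(expected - self.n_points) > 1e-9:
            raise ValueError(
                f"n_points={self.n_points} inconsistent with "
                f"(stop-start)/step+1={expected}"
            )

    @property
    def wavelengths(self) -> np.ndarray:
        """Wavelength of every grid point, nm (exact arithmetic progression)."""
        return self.start_nm + self.step_nm * np.arange(self.n_points)

    def index_of(self, wavelength_nm: float) -> int:
        """Index of the grid point nearest ``wavelength_nm``."""
        i = int(round((wavelength_nm - self.start_nm) / self.step_nm))
        return min(max(i, 0), self.n_points - 1)

    def band_slice(self, lo_nm: float, hi_nm: float) -> slice:
        """Slice covering the closed wavelength interval [lo_nm, hi_nm]."""
        if lo_nm > hi_nm:
            raise ValueError("band lower bound exceeds upper bound")
        lo = int(np.ceil((lo_nm - self.start_nm) / self.step_nm - 1e-9))
        hi = int(np.floor((hi_nm - self.start_nm) / self.step_nm + 1e-9))
        lo = max(lo, 0)
        hi = min(hi, self.n_points - 1)
        if hi < lo:
            raise ValueError(f"band [{lo_nm}, {hi_nm}] nm contains no grid point")
        return slice(lo, hi + 1)

    def covers(self, wavelength_nm: float) -> bool:
        return self.start_nm - 1e-9 <= wavelength_nm <= self.stop_nm + 1e-9


def make_default_grid() -> WavelengthGrid:
    """The instrument's acquisition grid: 380–680 nm in 1 nm steps (301 points)."""
    n = int(round((DEFAULT_STOP_NM - DEFAULT_START_NM) / DEFAULT_STEP_NM)) + 1
    return WavelengthGrid(DEFAULT_START_NM, DEFAULT_STOP_NM, DEFAULT_STEP_NM, n)


@dataclass
class Spectrum:
    """One emission spectrum: intensities (detector counts) on a grid.

    ``intensities`` must be nonnegative for raw/smoothed stages; a
    normalized spectrum has band maximum exactly 1.  ``meta`` may carry a
    synthetic truth label (never consulted by classification).
    """

    grid: WavelengthGrid
    intensities: np.ndarray
    spectrum_id: str = "s0"
    stage: Stage = Stage.RAW
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (self.grid.n_points,):
            raise ValueError(
                f"intensities length {self.intensities.shape} does not match "
                f"grid n_points {self.grid.n_points}"
            )
        if self.stage in (Stage.RAW, Stage.SMOOTHED) and np.any(self.intensities < 0):
            raise ValueError(f"negative intensity in {self.stage.value} spectrum")

    def with_intensities(self, values: np.ndarray, stage: Stage) -> "Spectrum":
        return replace(self, intensities=np.asarray(values, dtype=float), stage=stage)

    def copy(self) -> "Spectrum":
        return replace(self, intensities=self.intensities.copy(), meta=dict(self.meta))


@dataclass
class LesionScan:
    """All spectra acquired over one lesion, sharing a single grid."""

    lesion_id: str
    spectra: list[Spectrum]
    diagnosis: Diagnosis = Diagnosis.UNKNOWN
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.spectra) < 1:
            raise ValueError("a scan needs at least one spectrum")
        g0 = self.spectra[0].grid
        for s in self.spectra[1:]:
            if s.grid != g0:
                raise ValueError("all spectra in a scan must share one grid")

    @property
    def grid(self) -> WavelengthGrid:
        return self.spectra[0].grid

    def __len__(self) -> int:
        return len(self.spectra)

    def intensity_matrix(self) -> np.ndarray:
        """(n_spectra, n_points) matrix of intensities."""
        return np.vstack([s.intensities for s in self.spectra])


# ---------------------------------------------------------------------------
# On-disk format: UTF-8, tab-separated.
#   # key = value           metadata lines (lesion_id and diagnosis required)
#   # s.<id>.<key> = value  per-spectrum metadata (e.g. synthetic truth label)
#   wavelength_nm  <id1> ...    single header row
#   380.0  12.0 ...             data rows, wavelengths strictly increasing
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("lesion_id", "diagnosis")
_SPECTRUM_META_PREFIX = "s."


def read_scan(path: str | Path) -> LesionScan:
    """Read a lesion scan from the tab-separated spectra format.

    Raises :class:`SpectraFormatError` naming the offending line for any
    malformed header, non-monotone wavelengths, negative intensities or
    ragged rows.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header: list[str] | None = None
    wavelengths: list[float] = []
    rows: list[list[float]] = []
    row_linenos: list[int] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise SpectraFormatError(
                        f"{path}:{lineno}: metadata line lacks '=': {line!r}"
                    )
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
                continue
            fields = line.split("\t")
            if header is None:
                if fields[0] != "wavelength_nm" or len(fields) < 2:
                    raise SpectraFormatError(
                        f"{path}:{lineno}: expected header "
                        f"'wavelength_nm<TAB>id...', got {line!r}"
                    )
                header = fields
                continue
            if len(fields) != len(header):
                raise SpectraFormatError(
                    f"{path}:{lineno}: expected {len(header)} columns, "
                    f"got {len(fields)}"
                )
            try:
                values = [float(v) for v in fields]
            except ValueError as exc:
                raise SpectraFormatError(f"{path}:{lineno}: {exc}") from None
            if wavelengths and values[0] <= wavelengths[-1]:
                raise SpectraFormatError(
                    f"{path}:{lineno}: wavelengths must be strictly increasing"
                )
            wavelengths.append(values[0])
            rows.append(values[1:])
            row_linenos.append(lineno)
    if header is None or not rows:
        raise SpectraFormatError(f"{path}: no data rows")
    for key in _REQUIRED_KEYS:
        if key not in meta:
            raise SpectraFormatError(f"{path}: missing required metadata '{key}'")

    wl = np.asarray(wavelengths)
    steps = np.diff(wl)
    step = float(steps[0]) if len(steps) else 1.0
    if len(steps) and not np.allclose(steps, step, atol=1e-9):
        raise SpectraFormatError(f"{path}: wavelength grid is not uniform")
    grid = WavelengthGrid(float(wl[0]), float(wl[-1]), step, len(wl))
    data = np.asarray(rows)  # (n_points, n_spectra)
    diagnosis = Diagnosis(meta.pop("diagnosis"))
    lesion_id = meta.pop("lesion_id")
    stage = Stage(meta.pop("stage", "raw"))
    if stage in (Stage.RAW, Stage.SMOOTHED):
        # difference-stage spectra may legitimately be negative
        for i, row in enumerate(rows):
            if any(v < 0 for v in row):
                raise SpectraFormatError(
                    f"{path}:{row_linenos[i]}: negative intensity"
                )
    spectrum_meta: dict[str, dict[str, str]] = {}
    for key in [k for k in meta if k.startswith(_SPECTRUM_META_PREFIX)]:
        value = meta.pop(key)
        try:
            _, sid, mkey = key.split(".", 2)
        except ValueError:
            raise SpectraFormatError(
                f"{path}: malformed per-spectrum metadata key {key!r}"
            ) from None
        spectrum_meta.setdefault(sid, {})[mkey] = value
    spectra = [
        Spectrum(
            grid,
            data[:, j],
            spectrum_id=header[j + 1],
            stage=stage,
            meta=spectrum_meta.get(header[j + 1], {}),
        )
        for j in range(data.shape[1])
    ]
    return LesionScan(lesion_id, spectra, diagnosis=diagnosis, meta=meta)


def write_scan(scan: LesionScan, path: str | Path) -> None:
    """Write a scan in the format read by :func:`read_scan` (round-trips)."""
    path = Path(path)
    stages = {s.stage for s in scan.spectra}
    if len(stages) > 1:
        raise ValueError("cannot write a scan with mixed stages")
    lines = [f"# lesion_id = {scan.lesion_id}", f"# diagnosis = {scan.diagnosis.value}"]
    stage = next(iter(stages))
    if stage is not Stage.RAW:
        lines.append(f"# stage = {stage.value}")
    for key, value in scan.meta.items():
        lines.append(f"# {key} = {value}")
    for s in scan.spectra:
        for key, value in s.meta.items():
            lines.append(f"# {_SPECTRUM_META_PREFIX}{s.spectrum_id}.{key} = {value}")
    lines.append("\t".join(["wavelength_nm"] + [s.spectrum_id for s in scan.spectra]))
    wl = scan.grid.wavelengths
    data = scan.intensity_matrix()  # (n_spectra, n_points)
    for i in range(scan.grid.n_points):
        row = [repr(float(wl[i]))] + [repr(float(v)) for v in data[:, i]]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
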