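"""NIR spectrum containers and preprocessing.

Spectra live on a fixed 400–1700 nm grid with 5 nm steps (261 channels),
as acquired in diffuse reflectance by an on-line sensor that averages
300 scans per measurement.  Preprocessing covers scan averaging, the two
scatter corrections (standard normal variate, multiplicative scatter
correction) and the Savitzky–Golay first derivative.  All operations are
grid-preserving.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "DEFAULT_DERIV_POLYORDER",
    "DEFAULT_DERIV_WINDOW",
    "Spectrum",
    "SpectraSet",
    "average_scans",
    "default_grid",
    "first_derivative",
    "msc",
    "snv",
]

WAVELENGTH_MIN = 400.0
WAVELENGTH_MAX = 1700.0
WAVELENGTH_STEP = 5.0
DEFAULT_DERIV_WINDOW = 5
DEFAULT_DERIV_POLYORDER = 2

#: |b| below this in the MSC affine fit is treated as degenerate.
_MSC_SLOPE_TOL = 1e-10


def default_grid() -> np.ndarray:
    """The instrument grid: 400–1700 nm inclusive, 5 nm step (261 ch)."""
    return np.arange(WAVELENGTH_MIN, WAVELENGTH_MAX + WAVELENGTH_STEP, WAVELENGTH_STEP)


def _validate_grid(wavelengths: np.ndarray) -> None:
    if wavelengths.ndim != 1 or wavelengths.size < 2:
        raise ValueError("wavelength grid must be 1-D with >= 2 channels")
    steps = np.diff(wavelengths)
    if np.any(steps <= 0):
        raise ValueError("wavelength grid must be strictly increasing")
    if not np.allclose(steps, steps[0]):
        raise ValueError("wavelength grid must have a uniform step")


@dataclass
class Spectrum:
    """A single spectrum on a uniform wavelength grid."""

    wavelengths: np.ndarray
    values: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        _validate_grid(self.wavelengths)
        if self.values.shape != self.wavelengths.shape:
            raise ValueError(
                f"value count {self.values.shape} does not match grid "
                f"{self.wavelengths.shape}"
            )

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])

    @property
    def n_channels(self) -> int:
        return int(self.wavelengths.size)


@dataclass
class SpectraSet:
    """An ordered collection of spectra sharing one wavelength grid.

    ``values`` has shape (n_samples, n_channels).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        _validate_grid(self.wavelengths)
        if self.values.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"channel count {self.values.shape[1]} does not match grid "
                f"length {self.wavelengths.size}"
            )
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1:03d}" for i in range(self.values.shape[0])]
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match number of spectra")

    @property
    def n_samples(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.wavelengths.size)

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.wavelengths, self.values[i], self.sample_ids[i])

    def mean_spectrum(self) -> Spectrum:
        return Spectrum(self.wavelengths, self.values.mean(axis=0), "mean")

    def with_values(self, values: np.ndarray) -> "SpectraSet":
        return SpectraSet(self.wavelengths, values, list(self.sample_ids))

    # -- wide CSV format: sample_id,w0400,w0405,...,w1700 ------------------

    def to_frame(self) -> pd.DataFrame:
        cols = [f"w{int(round(w)):04d}" for w in self.wavelengths]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpectraSet":
        if "sample_id" not in df.columns:
            raise ValueError("wide spectra table needs a sample_id column")
        wave_cols = [c for c in df.columns if c != "sample_id"]
        try:
            wavelengths = np.array([float(c.lstrip("w")) for c in wave_cols])
        except ValueError:
            raise ValueError(
                "wavelength columns must be named like w0400, w0405, ..."
            ) from None
        return cls(
            wavelengths=wavelengths,
            values=df[wave_cols].to_numpy(dtype=float),
            sample_ids=[str(s) for s in df["sample_id"]],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectraSet":
        return cls.from_frame(pd.read_csv(path))


def _common_grid(scans: Sequence[Spectrum]) -> np.ndarray:
    grid = scans[0].wavelengths
    for s in scans[1:]:
        if s.wavelengths.shape != grid.shape or not np.array_equal(
            s.wavelengths, grid
        ):
            raise ValueError("scans do not share a common wavelength grid")
    return grid


def average_scans(scans: "SpectraSet | Sequence[Spectrum]") -> Spectrum:
    """Channel-wise arithmetic mean of repeated scans of one sample."""
    if isinstance(scans, SpectraSet):
        if scans.n_samples < 1:
            raise ValueError("need at least one scan")
        return scans.mean_spectrum()
    scans = list(scans)
    if not scans:
        raise ValueError("need at least one scan")
    grid = _common_grid(scans)
    values = np.mean([s.values for s in scans], axis=0)
    return Spectrum(grid, values, "mean")


# ---------------------------------------------------------------------------
# Array-level transforms (rows = spectra); public wrappers below.


def snv_transform(values: np.ndarray) -> np.ndarray:
    """Row-wise standard normal variate: mean 0, SD 1 (n−1 denominator)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant spectrum has zero variance; SNV undefined")
    return (values - mean) / sd


def msc_transform(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is fit by least squares as x ≈ a + b·reference and
    corrected to (x − a)/b.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (values.shape[1],):
        raise ValueError("reference length does not match channel count")
    ref_c = reference - reference.mean()
    denom = float(ref_c @ ref_c)
    if denom == 0:
        raise ValueError("constant reference spectrum; MSC undefined")
    b = (values - values.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(np.abs(b) < _MSC_SLOPE_TOL):
        raise ValueError(
            "degenerate MSC fit: |slope| below tolerance for at least one spectrum"
        )
    b = b[:, None]
    a = values.mean(axis=1, keepdims=True) - b * reference.mean()
    return (values - a) / b


def derivative_transform(
    values: np.ndarray,
    step: float,
    window: int = DEFAULT_DERIV_WINDOW,
    polyorder: int = DEFAULT_DERIV_POLYORDER,
) -> np.ndarray:
    """Savitzky–Golay first derivative along the wavelength axis
    (units value·nm⁻¹); edge channels come from the edge polynomial fit,
    so the grid is preserved."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if window > values.shape[1]:
        raise ValueError(
            f"derivative window {window} exceeds channel count {values.shape[1]}"
        )
    if polyorder >= window:
        raise ValueError("polynomial order must be smaller than the window")
    return savgol_filter(
        values, window_length=window, polyorder=polyorder, deriv=1,
        delta=step, axis=1, mode="interp",
    )


# ---------------------------------------------------------------------------
# Public wrappers on the containers


def _apply(obj, func):
    if isinstance(obj, Spectrum):
        out = func(obj.values[None, :])[0]
        return Spectrum(obj.wavelengths, out, obj.sample_id)
    if isinstance(obj, SpectraSet):
        return obj.with_values(func(obj.values))
    raise TypeError(f"expected Spectrum or SpectraSet, got {type(obj).__name__}")


def snv(spectra):
    """Standard normal variate transform of a Spectrum or SpectraSet."""
    return _apply(spectra, snv_transform)


def msc(spectra, reference: "Spectrum | np.ndarray"):
    """Multiplicative scatter correction against ``reference`` (typically
    the mean spectrum of the training set)."""
    ref = reference.values if isinstance(reference, Spectrum) else np.asarray(reference)
    return _apply(spectra, lambda v: msc_transform(v, ref))


def first_derivative(
    spectra,
    window: int = DEFAULT_DERIV_WINDOW,
    polyorder: int = DEFAULT_DERIV_POLYORDER,
):
    """Savitzky–Golay first derivative of a Spectrum or SpectraSet."""
    step = spectra.step
    return _apply(
        spectra, lambda v: derivative_transform(v, step, window, polyorder)
    )
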