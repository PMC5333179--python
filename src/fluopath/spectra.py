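"""Wavelength grids, spectral distributions and fluorophore photophysics.

Everything spectral in the renderer lives on a fixed uniform wavelength grid
(default 300-800 nm in 1 nm steps).  A :class:`Fluorophore` carries the
excitation spectrum ``f_x`` (peak-normalized), the emission spectrum ``f_m``,
the quantum yield ``phi`` and the molar absorptivity ``epsilon`` at the
excitation maximum; a :class:`DyeSolution` adds the molar concentration and
yields the fluorescence absorption coefficient

    mu_a^f(lambda) = ln(10) * epsilon * C * f_x_hat(lambda)      [mm^-1]

under the Beer-Lambert convention (``epsilon`` in cm^-1 M^-1, converted to mm
once at evaluation).  The probability that an absorbed photon at ``lambda_x``
produces fluorescence is

    p_x(lambda_x) = phi * mu_a^f(lambda_x) / mu_a(lambda_x)

and the emitted wavelength follows the discrete emission probability mass

    p_m(lambda_m) = f_m(lambda_m) * dlambda / integral(f_m)

so that the joint fluorescence probability factorizes,
``p_f(lambda_x, lambda_m) = p_x(lambda_x) * p_m(lambda_m)``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "Fluorophore",
    "DyeSolution",
    "DEFAULT_GRID",
    "make_gaussian_fluorophore",
    "dye_preset",
    "list_presets",
    "emission_pdf",
    "sample_emission_wavelength",
    "fluorescence_absorption_coefficient",
    "excitation_probability",
    "fluorescence_probability",
    "read_spectrum",
    "write_spectrum",
]

LN10 = math.log(10.0)

#: relative floor below which synthetic Gaussian spectra are clipped to zero,
#: giving them finite support like measured dye spectra
GAUSSIAN_SUPPORT_FLOOR = 1e-6


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid in nanometres."""

    lambda_min: float = 300.0
    lambda_max: float = 800.0
    delta_lambda: float = 1.0

    def __post_init__(self):
        if not self.lambda_min < self.lambda_max:
            raise ValueError("lambda_min must be < lambda_max")
        if self.delta_lambda <= 0:
            raise ValueError("delta_lambda must be positive")
        n = (self.lambda_max - self.lambda_min) / self.delta_lambda
        if abs(n - round(n)) > 1e-9:
            raise ValueError("grid span must be an integer number of steps")

    @property
    def n(self) -> int:
        return int(round((self.lambda_max - self.lambda_min) / self.delta_lambda)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.lambda_min + self.delta_lambda * np.arange(self.n)

    def index(self, lam: float) -> int:
        """Nearest grid index for an on-grid wavelength."""
        i = int(round((lam - self.lambda_min) / self.delta_lambda))
        if i < 0 or i >= self.n:
            raise ValueError(f"wavelength {lam} nm outside grid "
                             f"[{self.lambda_min}, {self.lambda_max}]")
        return i

    def contains(self, lam: float) -> bool:
        return self.lambda_min <= lam <= self.lambda_max


DEFAULT_GRID = WavelengthGrid()


@dataclass
class Spectrum:
    """Nonnegative tabulated function of wavelength on a uniform grid.

    Evaluation off the grid is by linear interpolation and is zero outside
    ``[lambda_min, lambda_max]``.
    """

    grid: WavelengthGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n,):
            raise ValueError(
                f"expected {self.grid.n} values, got {self.values.shape}")
        if np.any(self.values < 0):
            raise ValueError("spectrum values must be nonnegative")

    def __call__(self, lam):
        return np.interp(lam, self.grid.wavelengths, self.values,
                         left=0.0, right=0.0)

    @classmethod
    def constant(cls, value: float, grid: WavelengthGrid = DEFAULT_GRID
                 ) -> "Spectrum":
        return cls(grid, np.full(grid.n, float(value)))

    @classmethod
    def line(cls, lam: float, value: float = 1.0,
             grid: WavelengthGrid = DEFAULT_GRID) -> "Spectrum":
        """Monochromatic line: a single nonzero grid bin."""
        v = np.zeros(grid.n)
        v[grid.index(lam)] = value
        return cls(grid, v)

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class Fluorophore:
    """A fluorescent dye: spectra plus scalar photophysical constants.

    Parameters
    ----------
    f_x : Spectrum
        Excitation (absorption) spectrum, peak-normalized to 1.
    f_m : Spectrum
        Emission spectrum (relative units).
    phi : float
        Quantum yield, in [0, 1].
    epsilon : float
        Molar absorptivity at the excitation maximum, cm^-1 M^-1.
    mw : float
        Molecular weight in daltons (tabulated; not used in any computation).
    """

    name: str
    f_x: Spectrum
    f_m: Spectrum
    phi: float
    epsilon: float
    mw: float
    lambda_x_peak: float
    lambda_m_peak: float

    def __post_init__(self):
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("quantum yield must lie in [0, 1]")
        if self.epsilon <= 0:
            raise ValueError("molar absorptivity must be positive")
        if self.lambda_m_peak < self.lambda_x_peak:
            raise ValueError("Stokes shift violated: emission peak below "
                             "excitation peak")
        if abs(self.f_x.values.max() - 1.0) > 1e-9:
            raise ValueError("excitation spectrum must be peak-normalized")


@dataclass
class DyeSolution:
    """A fluorophore dissolved at molar concentration ``concentration`` (mol/L)."""

    fluorophore: Fluorophore
    concentration: float

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError("concentration must be nonnegative")

    def mu_a_f(self) -> np.ndarray:
        """Fluorescence absorption coefficient per grid bin, mm^-1."""
        f = self.fluorophore
        # epsilon [cm^-1 M^-1] * C [M] -> cm^-1; /10 -> mm^-1
        return LN10 * f.epsilon * self.concentration * f.f_x.values / 10.0


def _truncated_gaussian(wavelengths: np.ndarray, peak: float, fwhm: float
                        ) -> np.ndarray:
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    v = np.exp(-0.5 * ((wavelengths - peak) / sigma) ** 2)
    v[v < GAUSSIAN_SUPPORT_FLOOR] = 0.0
    return v


def make_gaussian_fluorophore(name: str, lambda_x_peak: float,
                              lambda_m_peak: float, fwhm_x: float,
                              fwhm_m: float, phi: float, epsilon: float,
                              mw: float,
                              grid: WavelengthGrid = DEFAULT_GRID
                              ) -> Fluorophore:
    """Build a fluorophore with Gaussian excitation/emission spectra.

    Synthetic stand-in for measured spectra; the Gaussians are clipped to zero
    below ``GAUSSIAN_SUPPORT_FLOOR`` of the peak so they have finite support.
    """
    if not (grid.contains(lambda_x_peak) and grid.contains(lambda_m_peak)):
        raise ValueError("spectral peaks must lie inside the wavelength grid")
    if fwhm_x <= 0 or fwhm_m <= 0:
        raise ValueError("FWHM must be positive")
    lam = grid.wavelengths
    f_x = Spectrum(grid, _truncated_gaussian(lam, lambda_x_peak, fwhm_x))
    f_m = Spectrum(grid, _truncated_gaussian(lam, lambda_m_peak, fwhm_m))
    return Fluorophore(name=name, f_x=f_x, f_m=f_m, phi=phi, epsilon=epsilon,
                       mw=mw, lambda_x_peak=lambda_x_peak,
                       lambda_m_peak=lambda_m_peak)


# Alexa Fluor family, the workhorse dyes of fluorescence microscopy.
# (name, mw [Da], lambda_x [nm], lambda_m [nm], phi, epsilon [cm^-1 M^-1])
_PRESETS = {
    "AF350": (410.0, 346.0, 442.0, 0.02, 19000.0),
    "AF488": (643.0, 495.0, 519.0, 0.92, 73000.0),
    "AF568": (792.0, 578.0, 603.0, 0.69, 88000.0),
    "AF633": (1200.0, 632.0, 647.0, 0.90, 159000.0),
}

#: default FWHM (nm) of the synthetic Gaussian stand-in spectra
PRESET_FWHM = 60.0


def list_presets() -> list[str]:
    return sorted(_PRESETS)


def dye_preset(name: str, grid: WavelengthGrid = DEFAULT_GRID) -> Fluorophore:
    """Packaged Alexa Fluor preset with Gaussian stand-in spectra."""
    key = name.upper().replace("ALEXA", "AF").replace(" ", "").replace(".", "")
    if key not in _PRESETS:
        raise KeyError(f"unknown dye preset {name!r}; available: {list_presets()}")
    mw, lx, lm, phi, eps = _PRESETS[key]
    return make_gaussian_fluorophore(key, lx, lm, PRESET_FWHM, PRESET_FWHM,
                                     phi, eps, mw, grid)


def emission_pdf(fluorophore: Fluorophore,
                 grid: WavelengthGrid | None = None) -> Spectrum:
    """Discrete emission probability mass p_m per grid bin.

    ``p_m(lambda) = f_m(lambda) * dlambda / integral(f_m)``, with the integral
    taken as the rectangle-rule sum on the same grid so the masses add to
    exactly one.
    """
    if grid is None:
        grid = fluorophore.f_m.grid
    vals = fluorophore.f_m(grid.wavelengths) if grid is not fluorophore.f_m.grid \
        else fluorophore.f_m.values
    total = vals.sum()
    if total <= 0:
        raise ValueError("emission spectrum is identically zero; "
                         "emission pdf undefined")
    return Spectrum(grid, vals / total)


def sample_emission_wavelength(pdf: Spectrum, u) -> float | np.ndarray:
    """Inverse-CDF sample of the discrete emission distribution.

    ``u`` may be a scalar or an array of uniforms in [0, 1).
    """
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u >= 1)):
        raise ValueError("u must lie in [0, 1)")
    cdf = np.cumsum(pdf.values)
    cdf /= cdf[-1]
    idx = np.searchsorted(cdf, u, side="right")
    lam = pdf.grid.wavelengths[idx]
    return float(lam) if lam.ndim == 0 else lam


def fluorescence_absorption_coefficient(solution: DyeSolution, lam: float
                                        ) -> float:
    """mu_a^f(lambda) in mm^-1 for a dye solution."""
    f = solution.fluorophore
    if not f.f_x.grid.contains(lam):
        raise ValueError(f"wavelength {lam} nm outside the spectral grid")
    return float(LN10 * f.epsilon * solution.concentration * f.f_x(lam) / 10.0)


def excitation_probability(solution: DyeSolution,
                           medium_total_absorption: float,
                           lambda_x: float) -> float:
    """p_x(lambda_x) = phi * mu_a^f(lambda_x) / mu_a(lambda_x)."""
    mu_af = fluorescence_absorption_coefficient(solution, lambda_x)
    mu_a = medium_total_absorption
    if mu_a <= 0:
        raise ValueError("total absorption coefficient must be positive")
    if mu_af > mu_a * (1 + 1e-12):
        raise ValueError("mu_a^f exceeds total absorption: inconsistent medium")
    return solution.fluorophore.phi * mu_af / mu_a


def fluorescence_probability(solution: DyeSolution,
                             medium_total_absorption: float,
                             lambda_x: float, lambda_m: float) -> float:
    """Joint fluorescence probability p_f = p_x(lambda_x) * p_m(lambda_m)."""
    p_x = excitation_probability(solution, medium_total_absorption, lambda_x)
    pdf = emission_pdf(solution.fluorophore)
    i = pdf.grid.index(lambda_m)
    return p_x * float(pdf.values[i])


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a two-column CSV ``wavelength_nm,value``."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["wavelength_nm", "value"])
        for lam, v in zip(spectrum.grid.wavelengths, spectrum.values):
            w.writerow([f"{lam:g}", repr(float(v))])


def read_spectrum(path: str | Path,
                  grid: WavelengthGrid = DEFAULT_GRID) -> Spectrum:
    """Read a two-column CSV and resample onto ``grid`` by linear interpolation.

    Wavelengths must be strictly increasing and values nonnegative; the
    spectrum is zero outside the tabulated range.
    """
    lams, vals = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header and header[0].strip().lower() != "wavelength_nm":
            # headerless file: first row is data
            lams.append(float(header[0]))
            vals.append(float(header[1]))
        for row in reader:
            if not row:
                continue
            lams.append(float(row[0]))
            vals.append(float(row[1]))
    lams = np.asarray(lams)
    vals = np.asarray(vals)
    if len(lams) < 2:
        raise ValueError("spectrum CSV needs at least two rows")
    if np.any(np.diff(lams) <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    if np.any(vals < 0):
        raise ValueError("spectrum values must be nonnegative")
    out = np.interp(grid.wavelengths, lams, vals, left=0.0, right=0.0)
    return Spectrum(grid, out)
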