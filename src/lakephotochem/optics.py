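"""Optical metrics of colored dissolved organic matter (CDOM).

CDOM absorbance decays roughly exponentially with wavelength,
``a(lambda) = a(ref) * exp(-S * (lambda - ref))``, and a handful of scalar
summaries of that curve are standard currency in browning studies:

* ``a440`` - Napierian absorption coefficient at 440 nm, the usual proxy for
  visible water color;
* ``E2:E3`` - ratio of Napierian absorption at 250 vs 365 nm, inversely
  related to DOM molecular size and charge-transfer character;
* ``SUVA254`` - *decadic* absorbance per meter at 254 nm normalised to DOC,
  an aromaticity proxy (the only decadic quantity in the package; everything
  else is Napierian);
* spectral slopes ``S_290-400`` and ``S_300-600`` fitted over fixed windows.

Fluorescence indices (FI, HIX, beta:alpha) are carried as pass-through inputs
elsewhere; computing them from excitation-emission matrices is out of scope.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    FitFailureError,
    InvalidArgumentError,
    InvalidInputError,
    OutOfRangeError,
    UndefinedMetricError,
)

LN10 = float(np.log(10.0))


@dataclass(frozen=True)
class AbsorbanceSpectrum:
    """A CDOM absorbance spectrum on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths
        Wavelength grid in nm, strictly increasing.
    a
        Napierian absorption coefficient in 1/m, non-negative.
    pathlength_m
        Cuvette pathlength used when the decadic absorbance was converted to
        a Napierian coefficient; retained for provenance only.
    """

    wavelengths: np.ndarray
    a: np.ndarray
    pathlength_m: float = 0.01

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        a = np.asarray(self.a, dtype=float)
        if wl.ndim != 1 or a.shape != wl.shape:
            raise InvalidInputError("wavelengths and a must be matching 1-D arrays")
        if wl.size < 2:
            raise InvalidInputError("spectrum needs at least two grid points")
        if not np.all(np.diff(wl) > 0):
            raise InvalidInputError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(a)):
            raise InvalidInputError("spectrum contains non-finite values")
        if np.any(a < 0):
            raise InvalidInputError("absorption coefficients must be >= 0")
        if self.pathlength_m <= 0:
            raise InvalidInputError("pathlength_m must be > 0")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "a", a)

    def covers(self, lo: float, hi: float) -> bool:
        return self.wavelengths[0] <= lo and self.wavelengths[-1] >= hi

    def scaled(self, c: float) -> "AbsorbanceSpectrum":
        """Return a copy with all coefficients multiplied by ``c > 0``."""
        if c <= 0:
            raise InvalidArgumentError("scale factor must be > 0")
        return dataclasses.replace(self, a=self.a * c)


@dataclass(frozen=True)
class OpticalMetrics:
    """Scalar optical summary of one sample.

    ``fi``, ``hix`` and ``beta_alpha`` are measured fluorescence indices
    passed through from the input tables, never computed here.
    """

    a440: float
    suva254: float | None
    e2e3: float
    s290_400: float
    s300_600: float
    fi: float | None = None
    hix: float | None = None
    beta_alpha: float | None = None


def napierian_at(spec: AbsorbanceSpectrum, wavelength: float | np.ndarray) -> float | np.ndarray:
    """Napierian absorption coefficient at ``wavelength`` (nm).

    Linear interpolation between bracketing grid points; exact on the grid.
    """
    wl = np.asarray(wavelength, dtype=float)
    if np.any(wl < spec.wavelengths[0]) or np.any(wl > spec.wavelengths[-1]):
        raise OutOfRangeError(
            f"wavelength outside spectrum range "
            f"[{spec.wavelengths[0]:g}, {spec.wavelengths[-1]:g}] nm"
        )
    out = np.interp(wl, spec.wavelengths, spec.a)
    return float(out) if np.isscalar(wavelength) else out


def e2e3(spec: AbsorbanceSpectrum) -> float:
    """E2:E3 ratio a(250)/a(365); undefined when a(365) = 0."""
    a250 = napierian_at(spec, 250.0)
    a365 = napierian_at(spec, 365.0)
    if a365 == 0:
        raise UndefinedMetricError("a(365) = 0; E2:E3 undefined")
    return a250 / a365


def suva254(spec: AbsorbanceSpectrum, doc: float) -> float:
    """SUVA254 in L mg-C^-1 m^-1: decadic absorbance per meter at 254 nm / DOC."""
    if doc <= 0:
        raise InvalidArgumentError("doc must be > 0")
    return napierian_at(spec, 254.0) / LN10 / doc


def fit_spectral_slope(
    spec: AbsorbanceSpectrum, lo: float, hi: float, min_points: int = 10
) -> float:
    """Spectral slope S (1/nm) over [lo, hi] by log-linear least squares.

    Ordinary least squares of ln a vs wavelength; the negated slope is
    returned, so decaying spectra yield positive S.  Requires at least
    ``min_points`` grid points with a > 0 inside the window.
    """
    if hi <= lo:
        raise InvalidArgumentError("window must satisfy lo < hi")
    sel = (spec.wavelengths >= lo) & (spec.wavelengths <= hi) & (spec.a > 0)
    if int(sel.sum()) < min_points:
        raise FitFailureError(
            f"only {int(sel.sum())} positive points in [{lo:g}, {hi:g}] nm "
            f"(need >= {min_points})"
        )
    slope = np.polyfit(spec.wavelengths[sel], np.log(spec.a[sel]), 1)[0]
    return float(-slope)


def metrics(
    spec: AbsorbanceSpectrum,
    doc: float | None = None,
    fi: float | None = None,
    hix: float | None = None,
    beta_alpha: float | None = None,
) -> OpticalMetrics:
    """Compute the full optical summary for one sample."""
    return OpticalMetrics(
        a440=napierian_at(spec, 440.0),
        suva254=None if doc is None else suva254(spec, doc),
        e2e3=e2e3(spec),
        s290_400=fit_spectral_slope(spec, 290.0, 400.0),
        s300_600=fit_spectral_slope(spec, 300.0, 600.0),
        fi=fi,
        hix=hix,
        beta_alpha=beta_alpha,
    )


def read_spectrum_csv(path) -> AbsorbanceSpectrum:
    """Read a two-column CSV (wavelength_nm, a_per_m) with a header line."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise InvalidInputError(f"{path}: expected two columns (wavelength_nm, a_per_m)")
    return AbsorbanceSpectrum(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))
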