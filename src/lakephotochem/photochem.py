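"""Singlet-oxygen photochemistry: quantum yields, light fields, and screening.

The chain implemented here follows standard aquatic-photochemistry practice:

1.  **Probe kinetics.**  Furfuryl alcohol (FFA) decays pseudo-first-order in
    the presence of singlet oxygen; the observed rate constant reports the
    in-vial steady state, ``[1O2]ss,exp = k_obs / k_rxn,FFA``.

2.  **Actinometry.**  A p-nitroanisole (PNA)/pyridine actinometer run in
    parallel calibrates the lamp: its quantum yield is a linear function of
    pyridine concentration, so the PNA loss rate fixes the absolute photon
    flux scale of the reference spectrum.

3.  **Apparent quantum yield.**  ``Phi = [1O2]ss,exp * k_d / R_a`` where
    ``k_d`` is the pseudo-first-order deactivation rate constant of 1O2 by
    water and ``R_a`` the rate of light absorption by the sample over
    290-550 nm.

4.  **Field steady state.**  The depth-averaged euphotic-zone concentration

    ``[1O2]ss = (Phi / k_d) * CF *
      sum_lambda Z_lambda / z_eu * (1 - exp(-Kd_lambda * z_eu))
                * (1 - f_backscatter) * f_abs,CDOM``

    with the euphotic depth and diffuse attenuation both empirical functions
    of DOC (``z_eu = 4.6 / (0.15 * DOC**1.08) * 100`` cm;
    ``Kd = exp(-0.01347 * lambda + 5.36 * DOC**0.157)``).  A near-surface
    variant replaces the depth-average factor ``(1-exp(-Kd z))/z`` by the
    surface absorption rate ``Kd``; an epilimnion variant reuses the
    depth-average form with a user-supplied mixed-layer depth.

5.  **Screening.**  Contaminant half-lives ``t1/2 = ln 2 / (k_rxn * [1O2])``
    are benchmarked against the lake's hydraulic residence time tau via
    ``log10(t1/2 / tau)``: below 0 reaction outpaces flushing, 0-1 the two
    are comparable, above 1 flushing wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    InvalidArgumentError,
    InvalidConfigurationError,
    InvalidInputError,
    OutOfRangeError,
    SuspectResultWarning,
)
from .optics import AbsorbanceSpectrum, napierian_at

#: Seconds in the 30.44-day month used for half-life unit conversion.
SECONDS_PER_MONTH = 30.44 * 86400.0

#: Wavelength window (nm) for quantum yields and light-field summations.
LAMBDA_LO, LAMBDA_HI = 290.0, 550.0


@dataclass(frozen=True)
class PhotoConstants:
    """Rate constants and actinometer coefficients.

    Defaults are conventional literature values at 25 degC and are meant to
    be overridden from a run configuration when better numbers are at hand:

    * ``k_rxn_ffa`` -- FFA + 1O2 bimolecular rate constant, 1.00e8 /M/s.
    * ``k_d_delta`` -- 1O2 deactivation by water, 2.76e5 /s (lifetime
      ~3.6 us in H2O).
    * ``phi_pna_slope``/``phi_pna_intercept`` -- PNA quantum yield vs
      pyridine concentration, ``Phi_PNA = 0.29 * [pyr] + 0.00029``.
    """

    k_rxn_ffa: float = 1.00e8
    k_d_delta: float = 2.76e5
    phi_pna_slope: float = 0.29
    phi_pna_intercept: float = 0.00029

    def __post_init__(self) -> None:
        for name in ("k_rxn_ffa", "k_d_delta", "phi_pna_slope", "phi_pna_intercept"):
            if getattr(self, name) <= 0:
                raise InvalidConfigurationError(f"{name} must be > 0")


@dataclass(frozen=True)
class LightField:
    """Wavelength-gridded daily-average solar irradiance plus correction factors.

    ``z_daily`` is in mol-photons cm^-2 s^-1 nm^-1 on the ``wavelengths``
    grid (nm).  ``cf`` is the non-clear-sky correction factor (0.60 for the
    study region), ``f_backscatter`` the fraction of sunlight backscattered
    out of the water column, ``f_abs_cdom`` the fraction of water-column
    absorbance attributable to CDOM (scalar or per wavelength),
    ``surface_reflection`` the air-water reflection loss, and
    ``pathlength_factor`` (>= 1) the geometric path-length enhancement for
    diffuse light underwater.
    """

    wavelengths: np.ndarray
    z_daily: np.ndarray
    cf: float = 0.60
    f_backscatter: float = 0.02
    f_abs_cdom: float | np.ndarray = 1.0
    surface_reflection: float = 0.066
    pathlength_factor: float = 1.2

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        z = np.asarray(self.z_daily, dtype=float)
        if wl.ndim != 1 or z.shape != wl.shape:
            raise InvalidInputError("wavelengths and z_daily must be matching 1-D arrays")
        if not np.all(np.diff(wl) > 0):
            raise InvalidInputError("wavelengths must be strictly increasing")
        if np.any(z < 0) or not np.all(np.isfinite(z)):
            raise InvalidInputError("z_daily must be finite and >= 0")
        for name in ("cf", "f_backscatter", "surface_reflection"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigurationError(f"{name} must lie in [0, 1]")
        fac = np.asarray(self.f_abs_cdom, dtype=float)
        if np.any(fac < 0) or np.any(fac > 1):
            raise InvalidConfigurationError("f_abs_cdom must lie in [0, 1]")
        if self.pathlength_factor < 1.0:
            raise InvalidConfigurationError("pathlength_factor must be >= 1")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "z_daily", z)

    def calibrated(self, scale: float = 1.0) -> np.ndarray:
        """Irradiance corrected for surface reflection and underwater pathlength."""
        return (
            self.z_daily * scale * (1.0 - self.surface_reflection) * self.pathlength_factor
        )


@dataclass(frozen=True)
class FirstOrderFit:
    """Observed pseudo-first-order rate constant with its standard error."""

    k_obs: float
    stderr: float


@dataclass(frozen=True)
class QuantumYieldResult:
    """Apparent 1O2 quantum yield and the quantities behind it."""

    phi_app: float
    one_o2_ss_exp: float
    ra: float
    phi_ratio_srnom: float | None = None


@dataclass(frozen=True)
class LakeOpticalModel:
    """DOC-driven optical sub-model of one lake: euphotic depth and Kd grid."""

    doc: float
    z_euphotic_cm: float
    kd_cm: np.ndarray  # diffuse attenuation, 1/cm, on the light-field grid
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        if self.z_euphotic_cm <= 0:
            raise InvalidArgumentError("z_euphotic_cm must be > 0")
        if np.any(np.asarray(self.kd_cm) <= 0):
            raise InvalidInputError("kd must be > 0 everywhere")

    @classmethod
    def from_doc(
        cls, doc: float, wavelengths: np.ndarray, kd_units: str = "m"
    ) -> "LakeOpticalModel":
        wl = np.asarray(wavelengths, dtype=float)
        kd = kd_lambda(doc, wl, units=kd_units)
        kd_cm = kd / 100.0 if kd_units == "m" else kd
        return cls(doc=doc, z_euphotic_cm=euphotic_depth(doc), kd_cm=kd_cm, wavelengths=wl)


@dataclass(frozen=True)
class SteadyState1O2:
    """Steady-state 1O2 concentrations (M) and the volumetric absorption rate."""

    c_euphotic: float
    c_near_surface: float
    ra_vol: float  # mol-photons / L / s absorbed, euphotic-zone depth average
    c_epilimnion: float | None = None


@dataclass(frozen=True)
class CompoundKinetics:
    """A contaminant and its 1O2 bimolecular rate constant (1/M/s)."""

    name: str
    k_rxn: float
    ph_measured: float | None = None

    def __post_init__(self) -> None:
        if self.k_rxn <= 0:
            raise InvalidArgumentError("k_rxn must be > 0")


FATE_FASTER = "faster_than_flushing"
FATE_COMPARABLE = "comparable"
FATE_SLOWER = "slower"


@dataclass(frozen=True)
class ScreeningResult:
    """Half-life vs flushing comparison for one compound in one lake."""

    compound: str
    t_half_months: float
    log10_ratio: float
    fate_class: str


# --------------------------------------------------------------------------
# probe kinetics and actinometry
# --------------------------------------------------------------------------


def fit_first_order(times, conc: np.ndarray | None = None) -> FirstOrderFit:
    """Fit ln(conc) vs time by OLS and return the negated slope.

    Accepts either ``(times, conc)`` arrays or a single kinetics-trace
    object exposing ``.times``/``.conc``.  ``times`` in seconds, ``conc``
    strictly positive; needs >= 4 points.
    """
    if conc is None:
        times, conc = times.times, times.conc
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.ndim != 1 or c.shape != t.shape:
        raise InvalidInputError("times and conc must be matching 1-D arrays")
    if t.size < 4:
        raise InvalidInputError("need at least 4 kinetic points")
    if np.any(c <= 0):
        raise InvalidInputError("concentrations must be strictly positive")
    if not np.all(np.diff(t) > 0):
        raise InvalidInputError("times must be strictly increasing")
    y = np.log(c)
    (slope, intercept), cov = np.polyfit(t, y, 1, cov=True)
    return FirstOrderFit(k_obs=float(-slope), stderr=float(np.sqrt(cov[0, 0])))


def pna_molar_absorptivity(wavelengths: np.ndarray) -> np.ndarray:
    """Synthetic PNA molar absorptivity model (1/M/cm).

    A single Gaussian band centred at 316 nm with peak 1.0e4 /M/cm stands in
    for the tabulated p-nitroanisole spectrum; generator and analyser share
    it, so actinometry round-trips are exact by construction.
    """
    wl = np.asarray(wavelengths, dtype=float)
    return 1.0e4 * np.exp(-0.5 * ((wl - 316.0) / 25.0) ** 2)


def pna_specific_absorption_rate(field: LightField, scale: float = 1.0) -> float:
    """Specific light-absorption rate of PNA under ``field`` (1/s per M PNA).

    ``2.303 * integral eps(lambda) * Z(lambda) dlambda * 1000`` in the
    optically dilute limit; ``scale`` multiplies the irradiance.
    """
    eps = pna_molar_absorptivity(field.wavelengths)
    integrand = np.log(10.0) * eps * field.z_daily * scale  # mol-photons cm^-3 s^-1 / M... per nm
    return float(np.trapezoid(integrand, field.wavelengths) * 1000.0)


def pna_quantum_yield(pyridine_M: float, constants: PhotoConstants) -> float:
    """PNA actinometer quantum yield at the given pyridine concentration."""
    if pyridine_M <= 0:
        raise InvalidArgumentError("pyridine_M must be > 0")
    phi = constants.phi_pna_slope * pyridine_M + constants.phi_pna_intercept
    if phi <= 0:
        raise InvalidConfigurationError("PNA quantum yield <= 0 under these coefficients")
    return phi


def actinometry_scale(
    pna_trace,
    pyridine_M: float,
    reference_field: LightField,
    constants: PhotoConstants = PhotoConstants(),
) -> float:
    """Irradiance scale factor calibrating the reference spectrum to the lamp.

    ``scale = k_obs,PNA / (Phi_PNA * specific absorption rate under the
    reference spectrum)``; multiplying the reference spectrum by ``scale``
    gives the calibrated in-vial spectrum.
    """
    phi_pna = pna_quantum_yield(pyridine_M, constants)
    k_obs = fit_first_order(pna_trace).k_obs
    rate_ref = pna_specific_absorption_rate(reference_field)
    if rate_ref <= 0:
        raise InvalidConfigurationError("reference spectrum absorbs no light in the PNA band")
    return k_obs / (phi_pna * rate_ref)


# --------------------------------------------------------------------------
# light absorption and quantum yield
# --------------------------------------------------------------------------


def rate_light_absorption(
    spec: AbsorbanceSpectrum,
    field: LightField,
    path_cm: float = 1.1,
    scale: float = 1.0,
) -> float:
    """Volumetric rate of light absorption by the sample, mol-photons/L/s.

    Trapezoidal sum over 290-550 nm of calibrated irradiance times the
    fraction absorbed along ``path_cm`` (vial inner diameter by default),
    normalised per unit volume.  Strictly increasing in any pointwise
    increase of a(lambda).
    """
    if path_cm <= 0:
        raise InvalidArgumentError("path_cm must be > 0")
    wl = field.wavelengths
    sel = (wl >= LAMBDA_LO) & (wl <= LAMBDA_HI)
    if not sel.any():
        raise InvalidInputError("light field does not cover 290-550 nm")
    wl = wl[sel]
    if not spec.covers(wl[0], wl[-1]):
        raise OutOfRangeError("absorbance spectrum does not cover the light-field window")
    a_cm = np.asarray(napierian_at(spec, wl)) / 100.0  # 1/m -> 1/cm
    frac = 1.0 - np.exp(-a_cm * path_cm)
    z = field.z_daily[sel] * scale
    return float(np.trapezoid(z * frac, wl) / path_cm * 1000.0)


def apparent_quantum_yield(
    k_obs_ffa: float,
    ra: float,
    constants: PhotoConstants = PhotoConstants(),
    phi_srnom: float | None = None,
) -> QuantumYieldResult:
    """Apparent 1O2 quantum yield from the FFA loss rate and absorption rate.

    ``[1O2]ss,exp = k_obs / k_rxn,FFA`` and ``Phi = [1O2]ss,exp * k_d / R_a``.
    Values outside (0, 1) raise :class:`SuspectResultWarning` but are
    returned unchanged.  ``phi_srnom`` (a quantum yield measured in parallel
    on Suwannee River NOM) enables the cross-study normalisation ratio.
    """
    if ra <= 0:
        raise InvalidArgumentError("ra must be > 0")
    if k_obs_ffa < 0:
        raise InvalidArgumentError("k_obs_ffa must be >= 0")
    c_exp = k_obs_ffa / constants.k_rxn_ffa
    phi = c_exp * constants.k_d_delta / ra
    if not 0.0 < phi < 1.0:
        warnings.warn(
            f"apparent quantum yield {phi:.3g} outside (0, 1)", SuspectResultWarning,
            stacklevel=2,
        )
    ratio = None if phi_srnom is None else phi / phi_srnom
    return QuantumYieldResult(phi_app=phi, one_o2_ss_exp=c_exp, ra=ra, phi_ratio_srnom=ratio)


# --------------------------------------------------------------------------
# lake optical sub-models
# --------------------------------------------------------------------------


def euphotic_depth(doc: float) -> float:
    """Euphotic-zone depth in cm from DOC: ``4.6 / (0.15 * DOC**1.08) * 100``.

    Empirical 1%-light-level model for humic temperate lakes; strictly
    decreasing in DOC.
    """
    if doc <= 0:
        raise InvalidArgumentError("doc must be > 0")
    return 4.6 / (0.15 * doc**1.08) * 100.0


def kd_lambda(
    doc: float, wavelength: float | np.ndarray, units: str = "m"
) -> float | np.ndarray:
    """Diffuse attenuation coefficient ``exp(-0.01347*lambda + 5.36*DOC**0.157)``.

    The empirical formula's output is interpreted as 1/m by default
    (``units="m"``); ``units="cm"`` returns the raw value read as 1/cm
    instead.  Strictly decreasing in wavelength, increasing in DOC; valid on
    290-550 nm.
    """
    if doc <= 0:
        raise InvalidArgumentError("doc must be > 0")
    if units not in ("m", "cm"):
        raise InvalidArgumentError("units must be 'm' or 'cm'")
    wl = np.asarray(wavelength, dtype=float)
    if np.any(wl < LAMBDA_LO) or np.any(wl > LAMBDA_HI):
        raise OutOfRangeError("wavelength outside 290-550 nm")
    out = np.exp(-0.01347 * wl + 5.36 * doc**0.157)
    return float(out) if np.isscalar(wavelength) else out


def steady_state_1o2(
    phi: QuantumYieldResult | float,
    field: LightField,
    lake: LakeOpticalModel,
    constants: PhotoConstants = PhotoConstants(),
    epilimnion_depth_cm: float | None = None,
) -> SteadyState1O2:
    """Depth-averaged steady-state [1O2] in the euphotic zone (and variants).

    Implements the light-field model term for term: irradiance corrected for
    surface reflection and pathlength, attenuated by ``(1 - exp(-Kd z)) / z``
    for the depth average (or ``Kd`` near the surface), scaled by the
    backscatter and CDOM-absorption fractions, the non-clear-sky factor, and
    ``Phi / k_d``.  Concentrations in M.
    """
    phi_app = phi.phi_app if isinstance(phi, QuantumYieldResult) else float(phi)
    if phi_app < 0:
        raise InvalidArgumentError("quantum yield must be >= 0")
    wl = field.wavelengths
    if wl[0] > LAMBDA_LO or wl[-1] < LAMBDA_HI:
        raise InvalidInputError("light field must cover 290-550 nm")
    sel = (wl >= LAMBDA_LO) & (wl <= LAMBDA_HI)
    wl_s = wl[sel]
    if np.max(np.diff(wl_s)) > 5.0:
        raise InvalidInputError("light-field grid has gaps > 5 nm in 290-550 nm")
    if lake.wavelengths.shape != wl.shape or not np.allclose(lake.wavelengths, wl):
        raise InvalidInputError("lake optical model grid does not match the light field")

    z_cal = field.calibrated()[sel]
    f_abs = np.broadcast_to(np.asarray(field.f_abs_cdom, dtype=float), wl.shape)[sel]
    common = z_cal * (1.0 - field.f_backscatter) * f_abs * 1000.0  # cm^-2 -> per L via cm^-3
    kd = lake.kd_cm[sel]

    def depth_average_rate(z_cm: float) -> float:
        if z_cm <= 0:
            raise InvalidArgumentError("depth must be > 0")
        term = (1.0 - np.exp(-kd * z_cm)) / z_cm  # 1/cm
        return float(field.cf * np.trapezoid(common * term, wl_s))

    ra_eu = depth_average_rate(lake.z_euphotic_cm)
    ra_ns = float(field.cf * np.trapezoid(common * kd, wl_s))
    scale = phi_app / constants.k_d_delta
    c_epi = None
    if epilimnion_depth_cm is not None:
        c_epi = scale * depth_average_rate(epilimnion_depth_cm)
    return SteadyState1O2(
        c_euphotic=scale * ra_eu,
        c_near_surface=scale * ra_ns,
        ra_vol=ra_eu,
        c_epilimnion=c_epi,
    )


# --------------------------------------------------------------------------
# contaminant screening
# --------------------------------------------------------------------------


def half_life(k_rxn: float, c: float, unit: str = "months") -> float:
    """Reaction half-life ``ln 2 / (k_rxn * c)`` in months (30.44-day months).

    ``unit="s"`` returns seconds.
    """
    if k_rxn <= 0 or c <= 0:
        raise InvalidArgumentError("k_rxn and c must be > 0")
    t_s = np.log(2.0) / (k_rxn * c)
    if unit == "s":
        return float(t_s)
    if unit == "months":
        return float(t_s / SECONDS_PER_MONTH)
    raise InvalidArgumentError("unit must be 'months' or 's'")


def classify_fate(log10_ratio: float) -> str:
    """Fate class from log10(t_half / tau); boundaries belong to the slower class."""
    if log10_ratio < 0:
        return FATE_FASTER
    if log10_ratio < 1:
        return FATE_COMPARABLE
    return FATE_SLOWER


def screen_compounds(
    compounds: list[CompoundKinetics], c: float, tau_years: float
) -> list[ScreeningResult]:
    """Half-life screening of each compound against lake flushing.

    ``log10_ratio = log10(t_half / tau)`` with both in months; class
    boundaries at 0 and 1 exactly.
    """
    if tau_years <= 0:
        raise InvalidArgumentError("tau_years must be > 0")
    tau_months = tau_years * 12.0
    out = []
    for cmp_ in compounds:
        t_half = half_life(cmp_.k_rxn, c)
        lr = float(np.log10(t_half / tau_months))
        out.append(
            ScreeningResult(
                compound=cmp_.name,
                t_half_months=t_half,
                log10_ratio=lr,
                fate_class=classify_fate(lr),
            )
        )
    return out
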