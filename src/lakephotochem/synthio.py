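"""Seeded generators for every input the pipeline consumes.

The module emulates the statistical structure of a long-term lake-monitoring
study — monthly water chemistry with planted linear trends, annual
seasonality and AR(1) noise; regional driver series with controllable
band-limited coherence to DOC; probe/actinometer photolysis kinetics built
by inverting the quantum-yield arithmetic; exponential CDOM spectra; a
smooth clear-sky-like solar spectrum; and a log-uniform contaminant rate
table — so every downstream stage can be exercised, and its hidden truth
recovered, without any external data.

All generators are deterministic under a fixed seed.  Defaults mirror the
study conditions the pipeline is meant for: 37 lakes dominated by drainage
systems with a couple of iron-rich seepage lakes, ~0.05 mg C/L/yr browning
trends, quantum yields of a few percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError, InvalidInputError
from .optics import AbsorbanceSpectrum
from .photochem import (
    CompoundKinetics,
    LightField,
    PhotoConstants,
    pna_specific_absorption_rate,
)

HYDRO_CLASSES = ("headwater_drainage", "chain_drainage", "mounded_seepage")
TILL_CLASSES = ("thin", "medium", "thick", "none")


@dataclass(frozen=True)
class LakeSpec:
    """Ground-truth attributes of one synthetic lake."""

    lake_id: str
    hydro_class: str
    till_class: str
    tau_years: float
    doc_baseline: float
    doc_trend: float
    color_per_doc: float
    suva_trend: float
    phi_true: float
    fe_um: float

    def __post_init__(self) -> None:
        if self.hydro_class not in HYDRO_CLASSES:
            raise InvalidArgumentError(f"unknown hydro_class {self.hydro_class!r}")
        if self.till_class not in TILL_CLASSES:
            raise InvalidArgumentError(f"unknown till_class {self.till_class!r}")
        if self.tau_years <= 0:
            raise InvalidArgumentError("tau_years must be > 0")
        if self.doc_baseline <= 0:
            raise InvalidArgumentError("doc_baseline must be > 0")
        if not 0.0 < self.phi_true < 0.1:
            raise InvalidArgumentError("phi_true must lie in (0, 0.1)")
        if self.fe_um < 0:
            raise InvalidArgumentError("fe_um must be >= 0")


@dataclass(frozen=True)
class MonthlyChemistrySeries:
    """Per-lake monthly water-chemistry record; gaps appear as NaN."""

    lake_id: str
    data: pd.DataFrame  # DatetimeIndex (month starts) x {doc,color,suva254,ph,so4_no3}

    def __post_init__(self) -> None:
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise InvalidInputError("data must be indexed by a DatetimeIndex")
        if not idx.is_monotonic_increasing or idx.has_duplicates:
            raise InvalidInputError("dates must be sorted and unique")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.data.index

    def series(self, parameter: str) -> pd.Series:
        return self.data[parameter]


@dataclass(frozen=True)
class DriverSeries:
    """Regional driver record on the same monthly calendar as the chemistry."""

    data: pd.DataFrame  # DatetimeIndex x {deposition,precipitation,soil_wetness,irradiance}


@dataclass(frozen=True)
class KineticsTrace:
    """A probe photolysis time course."""

    times: np.ndarray  # s, strictly increasing, >= 0
    conc: np.ndarray  # M, > 0
    species: str  # "FFA" | "PNA"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.conc, dtype=float)
        if t.size < 4:
            raise InvalidArgumentError("kinetics trace needs at least 4 points")
        if t[0] < 0 or not np.all(np.diff(t) > 0):
            raise InvalidInputError("times must be >= 0 and strictly increasing")
        if np.any(c <= 0):
            raise InvalidInputError("concentrations must be > 0")
        if self.species not in ("FFA", "PNA"):
            raise InvalidArgumentError("species must be 'FFA' or 'PNA'")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "conc", c)


@dataclass(frozen=True)
class BandCoupling:
    """Requested coherence of a driver with DOC in one period band.

    ``band`` is a (lo, hi) period range in months, ``magnitude`` the target
    coherence in [0, 1], and ``phase`` the target mean phase in [-pi, pi]
    under the convention that positive phase means DOC leads the driver.
    """

    band: tuple[float, float]
    magnitude: float
    phase: float

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not lo < hi:
            raise InvalidArgumentError("band must satisfy lo < hi")
        if not 0.0 <= self.magnitude <= 1.0:
            raise InvalidArgumentError("magnitude must lie in [0, 1]")
        if abs(self.phase) > np.pi:
            raise InvalidArgumentError("phase must lie in [-pi, pi]")


# class-conditional generator parameters; seepage lakes carry high dissolved
# iron (excited-state quenching) and low quantum yields, drainage lakes the
# reverse — the contrast the field comparisons are built around.
_CLASS_PARAMS = {
    "drainage": {"fe_log_mean": np.log(1.9), "fe_log_sd": 0.9, "fe_range": (0.3, 13.1),
                 "phi_range": (0.012, 0.037), "tau_log_mean": np.log(0.5), "tau_log_sd": 0.7},
    "seepage": {"fe_mean": 15.6, "fe_sd": 0.8, "fe_range": (13.5, 16.7),
                "phi_range": (0.006, 0.009), "tau_log_mean": np.log(3.0), "tau_log_sd": 0.4},
}


def gen_lakes(
    n: int, seed: int, hydro_classes: Sequence[str] | None = None
) -> list[LakeSpec]:
    """Generate ``n`` lake specifications.

    Drainage lakes dominate (p ~ 0.95, echoing a 35:2 drainage:seepage
    split); ``hydro_classes`` forces the class sequence when given.
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    if hydro_classes is not None and len(hydro_classes) != n:
        raise InvalidArgumentError("hydro_classes must have length n")
    rng = np.random.default_rng(seed)
    lakes = []
    for i in range(n):
        if hydro_classes is not None:
            hydro = hydro_classes[i]
        else:
            hydro = rng.choice(HYDRO_CLASSES, p=[0.50, 0.446, 0.054])
        seep = hydro == "mounded_seepage"
        par = _CLASS_PARAMS["seepage" if seep else "drainage"]
        if seep:
            till = "none"
            fe = float(np.clip(rng.normal(par["fe_mean"], par["fe_sd"]), *par["fe_range"]))
        else:
            till = rng.choice(("thin", "medium", "thick"), p=[0.45, 0.35, 0.20])
            fe = float(np.clip(rng.lognormal(par["fe_log_mean"], par["fe_log_sd"]),
                               *par["fe_range"]))
        lakes.append(
            LakeSpec(
                lake_id=f"L{i:03d}",
                hydro_class=str(hydro),
                till_class=str(till),
                tau_years=float(np.clip(
                    rng.lognormal(par["tau_log_mean"], par["tau_log_sd"]), 0.05, 20.0)),
                doc_baseline=float(rng.uniform(2.0, 10.0)),
                doc_trend=float(rng.normal(0.05, 0.03)),
                color_per_doc=1.0 / float(np.clip(rng.normal(0.095, 0.015), 0.06, 0.15)),
                suva_trend=float(rng.normal(-0.02, 0.015)),
                phi_true=float(rng.uniform(*par["phi_range"])),
                fe_um=fe,
            )
        )
    return lakes


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(n)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    w = rng.normal(0.0, innov_sd, n - 1)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + w[t - 1]
    return e


def gen_regional_forcing(
    months: int, seed: int, sd: float = 0.25, ar1_phi: float = 0.85
) -> np.ndarray:
    """A slow, persistent regional DOC anomaly (mg C/L) shared across lakes.

    Strongly autocorrelated AR(1) so its power sits at interannual periods:
    this is the common variation that makes cross-lake synchrony with
    regional drivers detectable at all, mirroring how browning lakes in one
    region co-respond to deposition and hydroclimate.
    """
    if months < 1:
        raise InvalidArgumentError("months must be >= 1")
    return _ar1(np.random.default_rng(seed), months, ar1_phi, sd)


def gen_chemistry(
    spec: LakeSpec,
    start: str = "1992-06-01",
    months: int = 240,
    seed: int = 0,
    seasonal_amp: float = 0.5,
    noise_sd: float = 0.15,
    ar1_phi: float = 0.15,
    missing_frac: float = 0.05,
    color_months: int | None = None,
    suva_start_month: int | None = None,
    doc_floor: float = 0.05,
    regional: np.ndarray | None = None,
) -> MonthlyChemistrySeries:
    """Monthly chemistry record: trend + annual sinusoid + AR(1) noise.

    ``doc(t) = baseline + trend * t_years + seasonal_amp * sin(2 pi t / 12)
    + AR(1)``, floored at ``doc_floor``; color tracks DOC through the
    planted color-to-DOC ratio; SUVA254 carries its own (usually negative)
    trend.  ``color_months`` truncates the color record (emulating a
    discontinued analysis) and ``suva_start_month`` delays the SUVA record.
    ``missing_frac`` knocks out values completely at random.  ``regional``
    (a months-long anomaly from :func:`gen_regional_forcing`, mg C/L) is
    added to the DOC signal so a lake set can share coherent interannual
    variation; omitted by default.

    The default noise autocorrelation (``ar1_phi = 0.15``) is mild on
    purpose: the seasonal Mann-Kendall test assumes serial independence and
    its false-positive rate inflates quickly with month-to-month
    correlation (roughly four-fold by phi = 0.5), so stronger persistence
    would leave the downstream trend stage without a valid null.
    """
    if months < 24:
        raise InvalidArgumentError("months must be >= 24 (two seasonal cycles)")
    if not 0.0 <= missing_frac < 1.0:
        raise InvalidArgumentError("missing_frac must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    t = np.arange(months, dtype=float)
    t_years = t / 12.0

    doc_clean = (
        spec.doc_baseline
        + spec.doc_trend * t_years
        + seasonal_amp * np.sin(2.0 * np.pi * t / 12.0)
    )
    if regional is not None:
        regional = np.asarray(regional, dtype=float)
        if regional.shape != (months,):
            raise InvalidArgumentError("regional must have one value per month")
        doc_clean = doc_clean + regional
    doc = np.clip(doc_clean + _ar1(rng, months, ar1_phi, noise_sd), doc_floor, None)
    color = np.clip(
        spec.color_per_doc * doc + rng.normal(0.0, noise_sd * spec.color_per_doc, months),
        0.0,
        None,
    )
    suva = np.clip(
        3.0
        + spec.suva_trend * t_years
        + 0.1 * seasonal_amp * np.sin(2.0 * np.pi * t / 12.0)
        + _ar1(rng, months, ar1_phi, 0.2 * noise_sd),
        0.0,
        None,
    )
    ph = 6.0 + 0.01 * t_years + _ar1(rng, months, ar1_phi, 0.5 * noise_sd)
    so4_no3 = np.clip(
        80.0 * np.exp(-t_years / 20.0) + _ar1(rng, months, ar1_phi, 20.0 * noise_sd),
        0.0,
        None,
    )

    df = pd.DataFrame(
        {"doc": doc, "color": color, "suva254": suva, "ph": ph, "so4_no3": so4_no3},
        index=pd.date_range(start, periods=months, freq="MS"),
    )
    if color_months is not None:
        df.loc[df.index[color_months:], "color"] = np.nan
    if suva_start_month is not None:
        df.loc[df.index[:suva_start_month], "suva254"] = np.nan
    if missing_frac > 0:
        for col in ("doc", "color", "suva254"):
            mask = rng.random(months) < missing_frac
            df.loc[mask, col] = np.nan
    return MonthlyChemistrySeries(lake_id=spec.lake_id, data=df)


_DRIVER_UNITS = {
    "deposition": (30.0, 10.0),  # ueq/L wet deposition equivalents
    "precipitation": (100.0, 30.0),  # mm/month
    "soil_wetness": (0.6, 0.1),  # volumetric fraction
    "irradiance": (180.0, 50.0),  # W/m2
}


def gen_drivers(
    chem: MonthlyChemistrySeries,
    couplings: Mapping[str, BandCoupling],
    seed: int = 0,
) -> DriverSeries:
    """Driver series with requested band-limited coherence to the DOC record.

    Each driver is built from the DOC record's band-limited Fourier
    component, phase-delayed by the requested coherence phase (positive
    phase = DOC leads the driver), mixed with independent noise that is a
    random-phase surrogate of that same component — spectrum-matched, so
    the signal-to-noise ratio, and hence the expected coherence, is uniform
    across the band and tracks the requested magnitude (exact at 0 and 1).
    The mixture is then mapped onto physically plausible units.
    """
    n = len(chem.data)
    x = chem.series("doc").interpolate(limit_direction="both").to_numpy(float)
    x = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
    freqs = np.fft.rfftfreq(n, d=1.0)
    with np.errstate(divide="ignore"):
        periods = np.where(freqs > 0, 1.0 / np.maximum(freqs, 1e-12), np.inf)
    X = np.fft.rfft(x)
    rng = np.random.default_rng(seed)
    cols = {}
    for name, coupling in couplings.items():
        lo, hi = coupling.band
        if lo < 2.0 or hi > n / 2.0:
            raise InvalidArgumentError(
                f"band {coupling.band} outside [2, {n / 2:g}] months"
            )
        mask = (periods >= lo) & (periods <= hi)
        if not mask.any():
            raise InvalidArgumentError(f"band {coupling.band} contains no Fourier modes")
        shared = np.fft.irfft(X * mask * np.exp(-1j * coupling.phase), n)
        if shared.std() > 0:
            shared = shared / shared.std()
        # spectrum-matched independent noise: random-phase surrogate of the
        # shared band component (DC/Nyquist handled by the band mask)
        amp = np.abs(X) * mask
        noise_band = np.fft.irfft(
            amp * np.exp(1j * rng.uniform(0.0, 2.0 * np.pi, amp.size)), n
        )
        if noise_band.std() > 0:
            noise_band = noise_band / noise_band.std()
        unit = (
            coupling.magnitude * shared
            + np.sqrt(max(0.0, 1.0 - coupling.magnitude**2)) * noise_band
        )
        offset, scale = _DRIVER_UNITS.get(name, (0.0, 1.0))
        cols[name] = offset + scale * unit
    return DriverSeries(data=pd.DataFrame(cols, index=chem.dates))


def gen_kinetics(
    phi_true: float,
    ra: float,
    species: str = "FFA",
    times: np.ndarray | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
    c0: float = 40e-6,
    constants: PhotoConstants = PhotoConstants(),
) -> KineticsTrace:
    """Probe photolysis trace inverted from the quantum-yield arithmetic.

    For FFA, ``k_obs = k_rxn,FFA * phi_true * ra / k_d``, the exact inverse
    of the downstream quantum-yield computation.  For PNA, ``phi_true`` is
    the actinometer quantum yield and ``ra`` its specific light-absorption
    rate (1/s), so ``k_obs = phi_true * ra``.  Noise is multiplicative
    lognormal with coefficient of variation ``noise_cv``.
    """
    if noise_cv < 0:
        raise InvalidArgumentError("noise_cv must be >= 0")
    if ra <= 0:
        raise InvalidArgumentError("ra must be > 0")
    if times is None:
        # a standard probe photolysis design: ~4 h irradiation sampled at 9
        # points, reaching >1 half-life at typical rates
        times = np.linspace(0.0, 14400.0, 9)
    times = np.asarray(times, dtype=float)
    if times.size < 4:
        raise InvalidArgumentError("need at least 4 time points")
    if species == "FFA":
        k_obs = constants.k_rxn_ffa * phi_true * ra / constants.k_d_delta
    elif species == "PNA":
        k_obs = phi_true * ra
    else:
        raise InvalidArgumentError("species must be 'FFA' or 'PNA'")
    conc = c0 * np.exp(-k_obs * times)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        rng = np.random.default_rng(seed)
        conc = conc * np.exp(rng.normal(-0.5 * sigma**2, sigma, times.size))
    return KineticsTrace(times=times, conc=conc, species=species)


def gen_spectrum(
    a440: float, s_slope: float, grid: np.ndarray | None = None
) -> AbsorbanceSpectrum:
    """Exponential CDOM spectrum ``a(lambda) = a440 * exp(-S (lambda - 440))``."""
    if a440 <= 0:
        raise InvalidArgumentError("a440 must be > 0")
    if s_slope <= 0:
        raise InvalidArgumentError("s_slope must be > 0")
    wl = np.arange(250.0, 601.0) if grid is None else np.asarray(grid, dtype=float)
    return AbsorbanceSpectrum(wavelengths=wl, a=a440 * np.exp(-s_slope * (wl - 440.0)))


def gen_solar_spectrum(
    z_scale: float = 5e-10,
    grid: np.ndarray | None = None,
    tilt: float = 2.0,
    ozone_tau: float = 10.0,
    ozone_scale_nm: float = 13.0,
    **field_kwargs,
) -> LightField:
    """Smooth clear-sky-like daily-average solar spectrum on 290-550 nm.

    ``Z(lambda) = z_scale * (lambda/550)**tilt * exp(-ozone_tau *
    exp(-(lambda-290)/ozone_scale_nm))``: a power-law tilt standing in for
    the rising solar photon flux plus preferential short-wavelength
    scattering losses, cut off below ~320 nm by an exponential ozone
    (Hartley-Huggins) absorption edge.  ``z_scale`` is the irradiance at
    550 nm in mol-photons cm^-2 s^-1 nm^-1.  Remaining keyword arguments
    pass through to :class:`LightField` (cf, f_backscatter, ...).
    """
    if z_scale <= 0:
        raise InvalidArgumentError("z_scale must be > 0")
    wl = np.arange(290.0, 551.0) if grid is None else np.asarray(grid, dtype=float)
    rel = (wl / 550.0) ** tilt * np.exp(-ozone_tau * np.exp(-(wl - 290.0) / ozone_scale_nm))
    return LightField(wavelengths=wl, z_daily=z_scale * rel, **field_kwargs)


def gen_pna_trace(
    scale: float,
    pyridine_M: float,
    reference_field: LightField,
    times: np.ndarray | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
    constants: PhotoConstants = PhotoConstants(),
) -> KineticsTrace:
    """PNA actinometer trace under ``scale`` times the reference spectrum."""
    phi_pna = constants.phi_pna_slope * pyridine_M + constants.phi_pna_intercept
    rate = pna_specific_absorption_rate(reference_field, scale=scale)
    return gen_kinetics(
        phi_true=phi_pna,
        ra=rate,
        species="PNA",
        times=times,
        noise_cv=noise_cv,
        seed=seed,
        c0=10e-6,
        constants=constants,
    )


def gen_compounds(
    n: int = 106,
    k_min: float = 6.3e3,
    k_max: float = 3.7e9,
    seed: int = 0,
) -> list[CompoundKinetics]:
    """Log-uniform contaminant rate-constant table spanning [k_min, k_max]."""
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    rng = np.random.default_rng(seed)
    ks = np.exp(rng.uniform(np.log(k_min), np.log(k_max), n))
    ks[0], ks[-1] = k_min, k_max  # pin the published extremes of the table
    return [
        CompoundKinetics(name=f"compound_{i:03d}", k_rxn=float(k))
        for i, k in enumerate(ks)
    ]
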