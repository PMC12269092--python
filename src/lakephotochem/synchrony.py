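"""Wavelet coherence between environmental time series.

Workflow: each monthly series is linearly interpolated across small gaps,
shifted positive, Box-Cox transformed (maximum-likelihood lambda), linearly
detrended and z-scored; a complex Morlet (omega0 = 6) continuous wavelet
transform is taken on a logarithmic period grid; and for a pair of series
the per-pixel normalized cross-wavelet product

    w_x * conj(w_y) / (|w_x| |w_y|)

is averaged over times outside the cone of influence, over site pairs, and
over the scales of a period band.  The modulus of that average is the
band coherence magnitude (0..1 by construction) and its argument the mean
phase.  Phase sign convention: **positive phase means x leads y** (a
quarter-cycle delay of y against a 12-month oscillation in x gives
phase = +pi/2).

Phases map onto four relationship classes with boundaries at +/-pi/4 and
+/-3pi/4: positive in-phase [-pi/4, pi/4], lagged negative (pi/4, 3pi/4),
lagged positive (-3pi/4, -pi/4), negative antiphase beyond +/-3pi/4.
Boundary values go to the in-phase/antiphase side.

Band significance comes from Fourier phase-randomized surrogates of the y
series (autocorrelation preserved, one common random phase rotation shared
across sites per surrogate) with the permutation-test estimator
``p = (1 + #{surrogate >= observed}) / (n_surrogates + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal, stats

from .exceptions import (
    InsufficientDataError,
    InvalidArgumentError,
    InvalidInputError,
)

#: Named period bands (months) used throughout the analysis.
BANDS: dict[str, tuple[float, float]] = {
    "short": (3.0, 6.0),
    "intermediate": (12.0, 24.0),
    "long": (36.0, 72.0),
}

#: Morlet centre frequency for omega0 = 6 (cycles per unit time at scale 1).
_MORLET_FC = 6.0 / (2.0 * np.pi)
_WAVELET = pywt.ContinuousWavelet(f"cmor2.0-{_MORLET_FC:.10f}")
#: Cone-of-influence e-folding factor: sqrt(2) * (Torrence-Compo scale/period).
_COI_FACTOR = float(np.sqrt(2.0) * (6.0 + np.sqrt(38.0)) / (4.0 * np.pi))

PHASE_CLASSES = (
    "positive_in_phase",
    "lagged_positive",
    "lagged_negative",
    "negative_antiphase",
)


@dataclass(frozen=True)
class PreprocessedSeries:
    """A series after interpolation, Box-Cox, detrending, and z-scoring."""

    values: np.ndarray
    transform_lambda: float
    detrend_order: int = 1
    interpolated_fraction: float = 0.0


@dataclass(frozen=True)
class CWTResult:
    """Complex Morlet CWT coefficients with cone-of-influence mask."""

    coef: np.ndarray  # (n_periods, n_times) complex
    periods: np.ndarray  # months
    valid: np.ndarray  # bool, True outside the cone of influence


@dataclass(frozen=True)
class CoherenceResult:
    """Band-aggregated coherence magnitude, phase and classification."""

    band: tuple[float, float]
    magnitude: float
    mean_phase: float
    phase_class: str
    p_band: float | None = None
    n_points: int = 0
    band_name: str | None = None


def resolve_band(band) -> tuple[tuple[float, float], str | None]:
    if isinstance(band, str):
        if band not in BANDS:
            raise InvalidArgumentError(f"unknown band {band!r}; known: {sorted(BANDS)}")
        return BANDS[band], band
    lo, hi = float(band[0]), float(band[1])
    if not lo < hi:
        raise InvalidArgumentError("band must satisfy lo < hi")
    return (lo, hi), None


def preprocess(values, max_missing: float = 0.1) -> PreprocessedSeries:
    """Interpolate gaps, shift positive, Box-Cox, detrend, standardize.

    Needs >= 48 points; refuses series with more than ``max_missing``
    missing; infinities are rejected outright.
    """
    v = np.asarray(values, dtype=float).copy()
    if v.ndim != 1:
        raise InvalidInputError("series must be 1-D")
    if v.size < 48:
        raise InsufficientDataError(f"need >= 48 points, got {v.size}")
    if np.any(np.isinf(v)):
        raise InvalidInputError("series contains non-finite values")
    missing = np.isnan(v)
    frac = float(missing.mean())
    if frac > max_missing:
        raise InvalidInputError(f"{frac:.0%} missing exceeds the {max_missing:.0%} limit")
    if missing.any():
        idx = np.arange(v.size)
        v[missing] = np.interp(idx[missing], idx[~missing], v[~missing])
    if np.all(v == v[0]):
        raise InvalidInputError("constant series cannot be standardized")

    vmin = v.min()
    if vmin <= 0:
        span = v.max() - vmin
        v = v - vmin + 0.01 * (span if span > 0 else 1.0)
    v, lam = stats.boxcox(v)
    v = signal.detrend(v, type="linear")
    v = v / v.std()
    return PreprocessedSeries(
        values=v, transform_lambda=float(lam), detrend_order=1, interpolated_fraction=frac
    )


def periods_for_band(band, voices_per_octave: int = 24) -> np.ndarray:
    """Logarithmic period grid spanning a band edge to edge."""
    (lo, hi), _ = resolve_band(band)
    n = max(2, int(np.ceil(voices_per_octave * np.log2(hi / lo))) + 1)
    return np.geomspace(lo, hi, n)


def cwt_morlet(values, periods) -> CWTResult:
    """Complex Morlet (omega0=6) CWT on the given period grid (months).

    Periods must lie within [2, n/2].  The ``valid`` mask excludes the
    standard e-folding cone of influence at both record edges.
    """
    v = values.values if isinstance(values, PreprocessedSeries) else np.asarray(values, float)
    periods = np.asarray(periods, dtype=float)
    n = v.size
    if np.any(periods < 2.0) or np.any(periods > n / 2.0):
        raise InvalidArgumentError(f"periods must lie within [2, {n / 2:g}] months")
    scales = periods * _MORLET_FC
    coef, _ = pywt.cwt(v, scales, _WAVELET, method="fft")
    edge_dist = np.minimum(np.arange(n), np.arange(n)[::-1])
    valid = edge_dist[None, :] >= (_COI_FACTOR * periods)[:, None]
    return CWTResult(coef=coef, periods=periods, valid=valid)


def _pair_phasors(wx: CWTResult, wy: CWTResult) -> tuple[complex, int]:
    """Sum of unit cross-wavelet phasors over jointly valid pixels."""
    mask = wx.valid & wy.valid
    prod = wx.coef * np.conj(wy.coef)
    mag = np.abs(prod)
    ok = mask & (mag > 0)
    if not ok.any():
        return 0.0 + 0.0j, 0
    return complex((prod[ok] / mag[ok]).sum()), int(ok.sum())


def coherence(pairs, band, periods=None) -> CoherenceResult:
    """Band-aggregated wavelet coherence over a list of (x, y) site pairs.

    ``pairs`` is a sequence of (x, y) tuples of equal-length preprocessed
    series (arrays or :class:`PreprocessedSeries`).  The normalized
    cross-wavelet phasor is averaged over time (outside the cone of
    influence), sites, and the scales of ``band``; magnitude is the modulus
    of that average and mean phase its argument.
    """
    (lo, hi), name = resolve_band(band)
    if len(pairs) < 1:
        raise InvalidArgumentError("need at least one site pair")
    if periods is None:
        periods = periods_for_band((lo, hi))
    total = 0.0 + 0.0j
    count = 0
    for x, y in pairs:
        s, c = _pair_phasors(cwt_morlet(x, periods), cwt_morlet(y, periods))
        total += s
        count += c
    if count == 0:
        raise InsufficientDataError("no valid time-scale points outside the cone of influence")
    mean = total / count
    phase = float(np.angle(mean))
    return CoherenceResult(
        band=(lo, hi),
        magnitude=float(np.abs(mean)),
        mean_phase=phase,
        phase_class=phase_classify(phase),
        n_points=count,
        band_name=name,
    )


def phase_classify(phase: float) -> str:
    """Map a mean phase (radians, [-pi, pi]) onto its relationship class."""
    if not np.isfinite(phase) or abs(phase) > np.pi + 1e-12:
        raise InvalidArgumentError("phase must lie in [-pi, pi]")
    ap = abs(phase)
    if ap <= np.pi / 4:
        return "positive_in_phase"
    if ap >= 3 * np.pi / 4:
        return "negative_antiphase"
    return "lagged_negative" if phase > 0 else "lagged_positive"


def _phase_randomize(rfft_y: np.ndarray, rotation: np.ndarray, n: int) -> np.ndarray:
    """Apply a common random phase rotation to an rfft and invert it."""
    Y = rfft_y * rotation
    return np.fft.irfft(Y, n)


def band_significance(
    pairs,
    band,
    n_surrogates: int = 199,
    seed: int = 0,
    periods=None,
) -> tuple[float, CoherenceResult]:
    """Surrogate p-value for the band coherence magnitude.

    Surrogates are Fourier phase randomizations of every y series sharing
    one random rotation per surrogate (preserving each series'
    autocorrelation and the cross-site alignment of the surrogates); the
    x side and its wavelet transforms stay fixed.  Returns ``(p, observed)``
    with ``p = (1 + #{m_surr >= m_obs}) / (n_surrogates + 1)``.
    """
    if n_surrogates < 99:
        raise InvalidArgumentError("n_surrogates must be >= 99")
    (lo, hi), _ = resolve_band(band)
    if periods is None:
        periods = periods_for_band((lo, hi))
    observed = coherence(pairs, (lo, hi), periods)

    xs = [np.asarray(x.values if isinstance(x, PreprocessedSeries) else x, float)
          for x, _ in pairs]
    ys = [np.asarray(y.values if isinstance(y, PreprocessedSeries) else y, float)
          for _, y in pairs]
    n = ys[0].size
    wxs = [cwt_morlet(x, periods) for x in xs]
    # many pairs share one driver series: cache surrogate transforms per unique y
    unique: dict[bytes, int] = {}
    y_index = []
    uniq_fft = []
    for y in ys:
        key = y.tobytes()
        if key not in unique:
            unique[key] = len(uniq_fft)
            uniq_fft.append(np.fft.rfft(y))
        y_index.append(unique[key])

    rng = np.random.default_rng(seed)
    nf = uniq_fft[0].size
    exceed = 0
    for _ in range(n_surrogates):
        rotation = np.ones(nf, dtype=complex)
        hi_bin = nf - 1 if n % 2 == 0 else nf  # keep DC (and Nyquist) unrotated
        phases = rng.uniform(0.0, 2.0 * np.pi, max(0, hi_bin - 1))
        rotation[1:hi_bin] = np.exp(1j * phases)
        wys = [cwt_morlet(_phase_randomize(f, rotation, n), periods) for f in uniq_fft]
        total = 0.0 + 0.0j
        count = 0
        for wx, yi in zip(wxs, y_index):
            s, c = _pair_phasors(wx, wys[yi])
            total += s
            count += c
        if count and abs(total / count) >= observed.magnitude:
            exceed += 1
    p = (1.0 + exceed) / (n_surrogates + 1.0)
    return p, observed
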