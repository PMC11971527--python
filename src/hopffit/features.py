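"""Spectral features of regional BOLD signals.

The adaptive fitter is guided by the fractional amplitude of low-frequency
fluctuation (fALFF): the fraction of a signal's amplitude spectrum lying in
the low-frequency band (default 0.01-0.1 Hz).  Its unnormalized counterpart
ALFF (mean in-band amplitude) and the low-frequency power ratio p (the same
ratio computed on squared amplitudes) are provided for comparison, along with
the three normalization schemes (z-score, min-max, mean scaling) whose choice
the gradient descent is sensitive to.

Spectra are single-taper periodograms of the demeaned signal; the amplitude
spectrum is the square root of the periodogram.  fALFF and p are therefore
dimensionless ratios in [0, 1], while ALFF carries the signal's amplitude
units.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .exceptions import (
    DegenerateInputError,
    InvalidConfigurationError,
    UndefinedFeatureError,
)
from .simulate import RegionalTimeSeries

__all__ = [
    "SpectralFeatures",
    "bandpass",
    "compute_falff",
    "compute_alff",
    "compute_power_ratio",
    "compute_features",
    "normalize",
]

#: Default low-frequency band (Hz).
DEFAULT_BAND = (0.01, 0.1)

#: Butterworth order of the zero-phase band-pass filter.
FILTER_ORDER = 4


class SpectralFeatures:
    """Per-region fALFF, ALFF and power ratio with their band annotations."""

    def __init__(self, falff, alff, power_ratio, band, total_band):
        self.falff = np.asarray(falff, dtype=float)
        self.alff = np.asarray(alff, dtype=float)
        self.power_ratio = np.asarray(power_ratio, dtype=float)
        self.band = tuple(band)
        self.total_band = tuple(total_band)


def _check_band(low: float, high: float, nyquist: float) -> None:
    if not (0 <= low < high <= nyquist + 1e-12):
        raise InvalidConfigurationError(
            f"band ({low}, {high}) Hz must satisfy 0 <= low < high <= Nyquist ({nyquist} Hz)"
        )


def bandpass(
    ts: RegionalTimeSeries,
    low: float,
    high: float,
    *,
    order: int = FILTER_ORDER,
    trim_s: float = 0.0,
) -> RegionalTimeSeries:
    """Zero-phase Butterworth band-pass filtered copy of ``ts``.

    ``low = 0`` with ``high`` at the Nyquist frequency is treated as a
    pass-through (the signal is only demeaned).  ``trim_s`` seconds may be
    dropped from each end to discard residual filter edge effects (default
    0: the forward-backward filter with odd-reflection padding already
    suppresses them, and trimming changes the sample count).
    """
    nyq = ts.nyquist
    _check_band(low, high, nyq)
    x = ts.values - ts.values.mean(axis=0)
    if low <= 0 and high >= nyq - 1e-12:
        out = x
    else:
        wn_high = min(high / nyq, 1 - 1e-6)
        if low <= 0:
            sos = sps.butter(order, wn_high, btype="lowpass", output="sos")
        else:
            sos = sps.butter(order, [low / nyq, wn_high], btype="bandpass", output="sos")
        out = sps.sosfiltfilt(sos, x, axis=0)
    if trim_s > 0:
        n_trim = int(round(trim_s / ts.tr))
        if 2 * n_trim >= out.shape[0] - 1:
            raise InvalidConfigurationError(
                f"trim_s={trim_s} would remove the whole series"
            )
        out = out[n_trim : out.shape[0] - n_trim]
    return RegionalTimeSeries(out, ts.tr, band=(low, high))


def _amplitude_spectrum(ts: RegionalTimeSeries):
    """One-sided amplitude spectrum (sqrt periodogram) of the demeaned signal."""
    x = ts.values - ts.values.mean(axis=0)
    freqs = np.fft.rfftfreq(ts.n_samples, d=ts.tr)
    amp = np.abs(np.fft.rfft(x, axis=0)) / ts.n_samples
    return freqs, amp


def _band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    low, high = band
    return (freqs > low) & (freqs <= high + 1e-12) & (freqs > 0)


def _ratio_feature(ts, band, total_band, power: bool) -> np.ndarray:
    nyq = ts.nyquist
    _check_band(*band, nyq)
    _check_band(*total_band, nyq)
    if band[0] < total_band[0] - 1e-12 or band[1] > total_band[1] + 1e-12:
        raise InvalidConfigurationError(
            f"band {band} must be contained in total_band {total_band}"
        )
    freqs, amp = _amplitude_spectrum(ts)
    if power:
        amp = amp**2
    num = amp[_band_mask(freqs, band)].sum(axis=0)
    den = amp[_band_mask(freqs, total_band)].sum(axis=0)
    zero = den <= 0
    if np.any(zero):
        bad = int(np.flatnonzero(zero)[0])
        raise UndefinedFeatureError(
            f"zero total spectral power in region {bad}; ratio feature undefined"
        )
    return num / den


def compute_falff(
    ts: RegionalTimeSeries,
    band: tuple[float, float] = DEFAULT_BAND,
    total_band: tuple[float, float] | None = None,
) -> np.ndarray:
    """Fractional ALFF: in-band amplitude sum over total-band amplitude sum.

    ``total_band`` defaults to (0, Nyquist).  Result is in [0, 1] per region
    and invariant to rescaling the whole signal.
    """
    if total_band is None:
        total_band = (0.0, ts.nyquist)
    return _ratio_feature(ts, band, total_band, power=False)


def compute_alff(
    ts: RegionalTimeSeries, band: tuple[float, float] = DEFAULT_BAND
) -> np.ndarray:
    """ALFF: mean amplitude-spectrum value over the band (amplitude units)."""
    _check_band(*band, ts.nyquist)
    freqs, amp = _amplitude_spectrum(ts)
    mask = _band_mask(freqs, band)
    if not mask.any():
        raise InvalidConfigurationError(f"band {band} contains no frequency bin")
    return amp[mask].mean(axis=0)


def compute_power_ratio(
    ts: RegionalTimeSeries,
    band: tuple[float, float] = DEFAULT_BAND,
    total_band: tuple[float, float] | None = None,
) -> np.ndarray:
    """Low-frequency power ratio p: as fALFF but on squared amplitudes."""
    if total_band is None:
        total_band = (0.0, ts.nyquist)
    return _ratio_feature(ts, band, total_band, power=True)


def compute_features(
    ts: RegionalTimeSeries,
    band: tuple[float, float] = DEFAULT_BAND,
    total_band: tuple[float, float] | None = None,
) -> SpectralFeatures:
    """All three spectral features in one pass."""
    if total_band is None:
        total_band = (0.0, ts.nyquist)
    return SpectralFeatures(
        falff=compute_falff(ts, band, total_band),
        alff=compute_alff(ts, band),
        power_ratio=compute_power_ratio(ts, band, total_band),
        band=band,
        total_band=total_band,
    )


def normalize(vec: np.ndarray, scheme: str = "meanscale") -> np.ndarray:
    """Normalize a feature vector.

    ``zscore``    -> (x - mean) / std          (mean 0, SD 1)
    ``minmax``    -> (x - min) / (max - min)   (range [0, 1])
    ``meanscale`` -> x / mean(x)               (preserves between-region ratios)

    Mean scaling is the fitter's default: it reduces scale differences
    between features while preserving the relative activity levels across
    regions, which is what the heterogeneous parameters encode.
    """
    v = np.asarray(vec, dtype=float)
    if not np.all(np.isfinite(v)):
        raise DegenerateInputError("feature vector contains non-finite values")
    if scheme == "zscore":
        sd = v.std()
        if sd == 0:
            raise DegenerateInputError("zscore undefined: zero standard deviation")
        return (v - v.mean()) / sd
    if scheme == "minmax":
        lo, hi = v.min(), v.max()
        if hi == lo:
            raise DegenerateInputError("minmax undefined: max equals min")
        return (v - lo) / (hi - lo)
    if scheme == "meanscale":
        m = v.mean()
        if m == 0:
            raise DegenerateInputError("meanscale undefined: zero mean")
        return v / m
    raise InvalidConfigurationError(f"unknown normalization scheme {scheme!r}")
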