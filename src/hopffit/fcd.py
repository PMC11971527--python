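"""Functional connectivity dynamics (FCD).

The temporal fingerprint the fitter matches is the distribution of
similarities between time-windowed phase-interaction patterns.  Per time
point the phase-interaction matrix is P_ij(t) = cos(phi_i(t) - phi_j(t)),
with phi the analytic-signal (Hilbert) phase of the band-passed signal.
Sliding windows (default 30 TRs, stride 1 TR) average P over time; the FCD
matrix holds the cosine similarity between the vectorized (upper triangle,
diagonal excluded) mean-interaction matrices of every window pair, and its
upper-triangle values form the distribution compared across conditions with
the two-sample Kolmogorov-Smirnov distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats
from scipy.signal import hilbert

from .exceptions import DegenerateInputError, InvalidInputError
from .features import DEFAULT_BAND, bandpass
from .simulate import RegionalTimeSeries

__all__ = [
    "PhaseSeries",
    "FCDDistribution",
    "instantaneous_phase",
    "phase_interaction_matrix",
    "windowed_mean_interaction",
    "cosine_similarity",
    "fcd",
    "ks_distance",
]

#: Default sliding-window length in TRs.
DEFAULT_WINDOW = 30


@dataclass
class PhaseSeries:
    """T x N instantaneous phases in (-pi, pi]."""

    phases: np.ndarray
    tr: float
    band: tuple[float, float]

    def __post_init__(self) -> None:
        p = np.asarray(self.phases, dtype=float)
        if not np.all(np.isfinite(p)):
            raise InvalidInputError("phase series contains non-finite values")
        self.phases = p

    @property
    def n_samples(self) -> int:
        return self.phases.shape[0]

    @property
    def n_regions(self) -> int:
        return self.phases.shape[1]


@dataclass
class FCDDistribution:
    """M x M window-pair cosine-similarity matrix and its value multiset."""

    matrix: np.ndarray
    window_length: int
    stride: int

    @property
    def n_windows(self) -> int:
        return self.matrix.shape[0]

    @property
    def values(self) -> np.ndarray:
        """Upper-triangle (off-diagonal) entries, the FCD distribution."""
        m = self.n_windows
        return self.matrix[np.triu_indices(m, k=1)]

    @property
    def mean(self) -> float:
        """Mean of the FCD value distribution (0 when there is one window)."""
        v = self.values
        return float(v.mean()) if v.size else 0.0


def instantaneous_phase(
    ts: RegionalTimeSeries, band: tuple[float, float] = DEFAULT_BAND
) -> PhaseSeries:
    """Analytic-signal phase of the band-passed, demeaned signal."""
    filtered = bandpass(ts, *band)
    phases = np.angle(hilbert(filtered.values, axis=0))
    return PhaseSeries(phases, ts.tr, band)


def phase_interaction_matrix(ph: PhaseSeries, t: int) -> np.ndarray:
    """P_ij(t) = cos(phi_i(t) - phi_j(t)); symmetric with unit diagonal."""
    if not 0 <= t < ph.n_samples:
        raise InvalidInputError(f"time index {t} out of range [0, {ph.n_samples})")
    phi = ph.phases[t]
    return np.cos(phi[:, None] - phi[None, :])


def windowed_mean_interaction(
    ph: PhaseSeries, start: int, window_length: int = DEFAULT_WINDOW
) -> np.ndarray:
    """Elementwise mean of P(t) over ``window_length`` samples from ``start``."""
    if window_length < 1:
        raise InvalidInputError("window_length must be >= 1")
    if start < 0 or start + window_length > ph.n_samples:
        raise InvalidInputError(
            f"window [{start}, {start + window_length}) exceeds series of "
            f"length {ph.n_samples}"
        )
    acc = np.zeros((ph.n_regions, ph.n_regions))
    for t in range(start, start + window_length):
        acc += phase_interaction_matrix(ph, t)
    return acc / window_length


def cosine_similarity(v1: np.ndarray, v2: np.ndarray) -> float:
    """dot(v1, v2) / (||v1|| ||v2||), in [-1, 1]."""
    v1 = np.asarray(v1, dtype=float).ravel()
    v2 = np.asarray(v2, dtype=float).ravel()
    if v1.shape != v2.shape:
        raise InvalidInputError("vectors must have equal length")
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise DegenerateInputError("cosine similarity undefined for a zero vector")
    return float(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))


def fcd(
    ts: RegionalTimeSeries,
    window_length: int = DEFAULT_WINDOW,
    stride: int = 1,
    band: tuple[float, float] = DEFAULT_BAND,
) -> FCDDistribution:
    """Sliding-window FCD matrix of a regional time series.

    M = floor((T - window_length) / stride) + 1 windows; entry (t1, t2) is
    the cosine similarity between the vectorized windowed mean-interaction
    matrices of windows t1 and t2.  Windows near the edges that would not
    fit are dropped, never padded.
    """
    if window_length < 1 or stride < 1:
        raise InvalidInputError("window_length and stride must be >= 1")
    T = ts.n_samples
    if T < window_length:
        raise InvalidInputError(
            f"series of length {T} too short for window_length {window_length}"
        )
    ph = instantaneous_phase(ts, band)
    n = ph.n_regions
    iu = np.triu_indices(n, k=1)

    # P(t) for all t, vectorized: cos(a-b) = cos a cos b + sin a sin b
    cosp = np.cos(ph.phases)
    sinp = np.sin(ph.phases)
    p_upper = cosp[:, iu[0]] * cosp[:, iu[1]] + sinp[:, iu[0]] * sinp[:, iu[1]]

    # window means via cumulative sum along time
    csum = np.vstack([np.zeros((1, p_upper.shape[1])), np.cumsum(p_upper, axis=0)])
    starts = np.arange(0, T - window_length + 1, stride)
    win = (csum[starts + window_length] - csum[starts]) / window_length

    norms = np.linalg.norm(win, axis=1)
    if np.any(norms == 0):
        raise DegenerateInputError("zero-norm window vector; FCD undefined")
    unit = win / norms[:, None]
    matrix = np.clip(unit @ unit.T, -1.0, 1.0)
    np.fill_diagonal(matrix, 1.0)
    matrix = (matrix + matrix.T) / 2.0
    return FCDDistribution(matrix, window_length, stride)


def ks_distance(s1, s2) -> float:
    """Two-sample Kolmogorov-Smirnov distance (sup norm between ECDFs)."""
    s1 = np.asarray(s1, dtype=float).ravel()
    s2 = np.asarray(s2, dtype=float).ravel()
    if s1.size == 0 or s2.size == 0:
        raise InvalidInputError("KS distance requires two non-empty samples")
    return float(spstats.ks_2samp(s1, s2, method="asymp").statistic)
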