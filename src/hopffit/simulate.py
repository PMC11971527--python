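"""Stochastic Hopf (Stuart-Landau) whole-brain simulator.

Each region *i* obeys the normal form of a supercritical Hopf bifurcation,
written in real coordinates z_i = x_i + i*y_i and diffusively coupled through
the structural connectome C:

    dx_i/dt = (a_i - x_i^2 - y_i^2) x_i - w_i y_i + G * sum_j C_ij (x_j - x_i) + beta * eta_i(t)
    dy_i/dt = (a_i - x_i^2 - y_i^2) y_i + w_i x_i + G * sum_j C_ij (y_j - y_i) + beta * eta_i(t)

For a_i < 0 the node fluctuates noisily around a stable fixed point; for
a_i > 0 it settles on a limit cycle of radius sqrt(a_i) at angular frequency
w_i.  The x component emulates the regional BOLD signal.  Integration is
Euler-Maruyama with independent Gaussian noise streams for the x and y
equations of every region.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .connectome import WeightedConnectome
from .exceptions import (
    InvalidConfigurationError,
    InvalidInputError,
    NumericalInstabilityError,
)

try:  # pragma: no cover - exercised implicitly
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "ModelParameters",
    "RegionalTimeSeries",
    "simulate",
    "estimate_intrinsic_frequencies",
    "DEFAULT_NOISE_SD",
]

#: Blow-up guard: abort integration when any |z| exceeds this.
BLOWUP_LIMIT = 1e6

#: Default dynamical noise, as a diffusion coefficient (units 1/sqrt(s)).
#: Calibrated so each Euler step at the reference dt = 0.1 s receives
#: additive noise of standard deviation 0.02, the stated noise level of the
#: model: 0.02 / sqrt(0.1 s).
DEFAULT_NOISE_SD = 0.02 / np.sqrt(0.1)


@dataclass
class RegionalTimeSeries:
    """T x N signal matrix sampled every ``tr`` seconds.

    ``band`` optionally annotates the (low, high) Hz band the values were
    filtered to.
    """

    values: np.ndarray
    tr: float
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        if v.ndim != 2:
            raise InvalidInputError(f"time series must be T x N, got shape {v.shape}")
        if v.shape[0] < 2:
            raise InvalidInputError("time series must have T >= 2 samples")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("time series contains non-finite values")
        if self.tr <= 0:
            raise InvalidInputError(f"TR must be positive, got {self.tr}")
        self.values = v

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def nyquist(self) -> float:
        return 0.5 / self.tr

    def with_values(self, values: np.ndarray, band=None) -> "RegionalTimeSeries":
        return RegionalTimeSeries(values, self.tr, band if band is not None else self.band)


@dataclass
class ModelParameters:
    """Everything entering the coupled Stuart-Landau equations.

    Attributes
    ----------
    a:
        Length-N bifurcation parameters (dimensionless).
    G:
        Global coupling strength, >= 0.
    omega:
        Length-N intrinsic angular frequencies, rad/s.
    beta:
        Noise diffusion coefficient; the Euler step receives noise of SD
        ``beta * sqrt(dt)``.  The default corresponds to per-step noise of
        SD 0.02 at the reference step dt = 0.1 s.
    dt:
        Euler-Maruyama step, s (default 0.1).
    tr:
        Output sampling interval, s; must be an integer multiple of ``dt``.
    duration:
        Output length, s (T = round(duration / tr) samples are returned).
    burn_in:
        Discarded initial transient, s (default 60).
    seed:
        Seed for the noise streams.
    """

    a: np.ndarray
    G: float
    omega: np.ndarray
    beta: float = DEFAULT_NOISE_SD
    dt: float = 0.1
    tr: float = 2.0
    duration: float = 400.0
    burn_in: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        if self.a.shape != self.omega.shape:
            raise InvalidInputError(
                f"a and omega must have equal length, got {self.a.shape} vs {self.omega.shape}"
            )
        if self.G < 0:
            raise InvalidConfigurationError(f"G must be >= 0, got {self.G}")
        if self.beta < 0:
            raise InvalidConfigurationError(f"beta must be >= 0, got {self.beta}")
        if self.dt <= 0:
            raise InvalidConfigurationError(f"dt must be > 0, got {self.dt}")
        steps_per_tr = self.tr / self.dt
        if abs(steps_per_tr - round(steps_per_tr)) > 1e-9:
            raise InvalidConfigurationError(
                f"TR ({self.tr}) must be an integer multiple of dt ({self.dt})"
            )
        if self.duration <= 0:
            raise InvalidConfigurationError("duration must be positive")
        if self.burn_in < 0:
            raise InvalidConfigurationError("burn_in must be >= 0")

    @property
    def n(self) -> int:
        return self.a.shape[0]

    def replace(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


def _euler_maruyama_python(a, omega, G, C, noise, dt, sample_every, n_burn_steps, x0, y0):
    n_steps = noise.shape[0]
    n = a.shape[0]
    n_out = (n_steps - n_burn_steps) // sample_every
    out = np.empty((n_out, n))
    x = x0.copy()
    y = y0.copy()
    row_sum = C.sum(axis=1)
    k = 0
    for step in range(n_steps):
        r2 = x * x + y * y
        cx = C @ x - row_sum * x
        cy = C @ y - row_sum * y
        dx = (a - r2) * x - omega * y + G * cx
        dy = (a - r2) * y + omega * x + G * cy
        x = x + dt * dx + noise[step, :, 0]
        y = y + dt * dy + noise[step, :, 1]
        if np.max(x * x + y * y) > BLOWUP_LIMIT**2:
            return out[:k], step
        if step >= n_burn_steps and (step - n_burn_steps) % sample_every == sample_every - 1:
            out[k] = x
            k += 1
    return out[:k], -1


if _HAVE_NUMBA:

    @numba.njit(cache=True)
    def _euler_maruyama_numba(a, omega, G, C, noise, dt, sample_every, n_burn_steps, x0, y0):  # pragma: no cover
        n_steps = noise.shape[0]
        n = a.shape[0]
        n_out = (n_steps - n_burn_steps) // sample_every
        out = np.empty((n_out, n))
        x = x0.copy()
        y = y0.copy()
        row_sum = np.zeros(n)
        for i in range(n):
            s = 0.0
            for j in range(n):
                s += C[i, j]
            row_sum[i] = s
        k = 0
        limit2 = BLOWUP_LIMIT * BLOWUP_LIMIT
        for step in range(n_steps):
            cx = C @ x
            cy = C @ y
            blown = False
            for i in range(n):
                r2 = x[i] * x[i] + y[i] * y[i]
                dx = (a[i] - r2) * x[i] - omega[i] * y[i] + G * (cx[i] - row_sum[i] * x[i])
                dy = (a[i] - r2) * y[i] + omega[i] * x[i] + G * (cy[i] - row_sum[i] * y[i])
                x[i] = x[i] + dt * dx + noise[step, i, 0]
                y[i] = y[i] + dt * dy + noise[step, i, 1]
                if x[i] * x[i] + y[i] * y[i] > limit2:
                    blown = True
            if blown:
                return out[:k], step
            if step >= n_burn_steps and (step - n_burn_steps) % sample_every == sample_every - 1:
                out[k] = x
                k += 1
        return out[:k], -1


def simulate(params: ModelParameters, c: WeightedConnectome) -> RegionalTimeSeries:
    """Integrate the coupled Stuart-Landau system and return BOLD-like x.

    The x components are sampled every TR after the burn-in transient is
    discarded.  Noise is drawn independently for the x and y equation of
    every region, scaled by ``beta * sqrt(dt)``.  Bit-identical output for
    identical parameters and seed.

    Raises
    ------
    NumericalInstabilityError
        If any oscillator amplitude exceeds ``BLOWUP_LIMIT`` during
        integration; the message names the offending step.
    """
    n = c.n
    if params.n != n:
        raise InvalidInputError(
            f"parameter length {params.n} does not match connectome size {n}"
        )
    dt = params.dt
    sample_every = int(round(params.tr / dt))
    n_out = int(round(params.duration / params.tr))
    if n_out < 2:
        raise InvalidConfigurationError("duration must cover at least 2 TRs")
    n_burn_steps = int(round(params.burn_in / dt))
    n_steps = n_burn_steps + n_out * sample_every

    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    if params.beta > 0:
        noise = rng.normal(0.0, params.beta * np.sqrt(dt), size=(n_steps, n, 2))
    else:
        noise = np.zeros((n_steps, n, 2))
    # deterministic small random initial condition, also seed-controlled
    x0 = rng.uniform(-0.1, 0.1, size=n)
    y0 = rng.uniform(-0.1, 0.1, size=n)

    kernel = _euler_maruyama_numba if _HAVE_NUMBA else _euler_maruyama_python
    out, blow_step = kernel(
        np.ascontiguousarray(params.a, dtype=np.float64),
        np.ascontiguousarray(params.omega, dtype=np.float64),
        float(params.G),
        np.ascontiguousarray(c.weights, dtype=np.float64),
        noise,
        float(dt),
        sample_every,
        n_burn_steps,
        x0,
        y0,
    )
    if blow_step >= 0:
        raise NumericalInstabilityError(
            f"oscillator amplitude exceeded {BLOWUP_LIMIT:g} at integration step "
            f"{blow_step} (t = {blow_step * dt:.1f} s)"
        )
    return RegionalTimeSeries(out, params.tr)


def estimate_intrinsic_frequencies(
    ts: RegionalTimeSeries, band: tuple[float, float] = (0.01, 0.1)
) -> np.ndarray:
    """Per-region intrinsic angular frequency from the narrowband spectrum.

    Returns ``omega_i = 2 * pi * f_i`` where ``f_i`` is the peak frequency of
    region *i*'s power spectrum restricted to ``band`` (Hz).
    """
    low, high = band
    if not 0 < low < high <= ts.nyquist + 1e-12:
        raise InvalidConfigurationError(
            f"band {band} invalid for Nyquist frequency {ts.nyquist} Hz"
        )
    x = ts.values - ts.values.mean(axis=0)
    freqs = np.fft.rfftfreq(ts.n_samples, d=ts.tr)
    power = np.abs(np.fft.rfft(x, axis=0)) ** 2
    mask = (freqs >= low) & (freqs <= high)
    if not mask.any():
        raise InvalidConfigurationError(
            f"band {band} contains no resolvable frequency bin "
            f"(resolution {freqs[1]:.4g} Hz)"
        )
    band_freqs = freqs[mask]
    peak = np.argmax(power[mask], axis=0)
    return 2.0 * np.pi * band_freqs[peak]
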