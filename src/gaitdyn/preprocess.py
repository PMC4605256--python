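"""Detrending, velocity estimation and step detection for walking bouts.

The detrend removes interstride trends with an orthogonal-wavelet
procedure: the trend is the least-squares fit of the signal in the span of
the periodized Daubechies (8 vanishing moments) scaling functions at the
dyadic level whose scale first exceeds 2.5x the estimated stride period,
augmented with a linear ramp (so non-periodic drifts do not ring at the
signal edges).  The 16-tap filter is used because shorter Daubechies
filters leak too much stride-frequency energy into the trend space at deep
levels.  Subtracting an orthogonal projection makes the operation exactly
idempotent, and the detrended signal plus the removed trend reconstructs
the input exactly.

Velocity is the cumulative trapezoidal integral of the detrended
acceleration, detrended again with the same procedure to remove integration
drift.  Step onsets are the local maxima of the vertical velocity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import find_peaks, welch

from .core import BoutRejected, DataError, StepSeries, VelocitySignal

# Daubechies-8 orthonormal low-pass decomposition filter (16 taps);
# high-pass is its quadrature mirror
_DB_H = np.array(
    [
        0.05441584224308161,
        0.3128715909144659,
        0.6756307362980128,
        0.5853546836548691,
        -0.015829105256023893,
        -0.2840155429624281,
        0.00047248457399797254,
        0.128747426620186,
        -0.01736930100202211,
        -0.04408825393106472,
        0.013981027917015516,
        0.008746094047015655,
        -0.00487035299301066,
        -0.0003917403729959771,
        0.0006754494059985568,
        -0.00011747678400228192,
    ]
)
_DB_G = ((-1) ** np.arange(len(_DB_H))) * _DB_H[::-1]
_NTAPS = len(_DB_H)


def _analysis(x: np.ndarray):
    n = len(x)
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(_NTAPS)[None, :]) % n
    windows = x[idx]
    return windows @ _DB_H, windows @ _DB_G


def _synthesis(a: np.ndarray, d: np.ndarray) -> np.ndarray:
    n = 2 * len(a)
    x = np.zeros(n)
    k = 2 * np.arange(len(a))
    for m in range(_NTAPS):
        np.add.at(x, (k + m) % n, _DB_H[m] * a + _DB_G[m] * d)
    return x


def dwt(x: np.ndarray, level: int):
    """Periodized orthogonal DWT; returns (approx, [detail_level, ..., detail_1])."""
    if len(x) % (1 << level) != 0:
        raise DataError("length must be a multiple of 2**level")
    details = []
    a = np.asarray(x, dtype=float)
    for _ in range(level):
        a, d = _analysis(a)
        details.append(d)
    return a, details[::-1]


def idwt(approx: np.ndarray, details) -> np.ndarray:
    a = approx
    for d in details:
        a = _synthesis(a, d)
    return a


def detrend_level(sample_rate: float, stride_period_s: float) -> int:
    """Dyadic level whose scale first exceeds 2.5x the stride period.

    The extra octave of margin keeps gait dynamics slower than the stride
    frequency (down to half the stride frequency) out of the removed band.
    """
    return int(np.ceil(np.log2(sample_rate * 2.5 * stride_period_s)))


from functools import lru_cache


@lru_cache(maxsize=64)
def _scaling_basis(n: int, level: int) -> np.ndarray:
    """Columns: periodized level-``level`` scaling functions restricted to
    the first ``n`` samples, plus a constant and a linear ramp.

    The periodized scaling functions at one level are circular shifts of a
    single mother column, so only one inverse transform is needed.
    """
    block = 1 << level
    n_pad = ((n + block - 1) // block) * block
    m = n_pad // block
    zero_details = [np.zeros(n_pad >> (level - l)) for l in range(level)]
    a = np.zeros(m)
    a[0] = 1.0
    mother = idwt(a, zero_details)
    cols = np.empty((n, m + 2))
    for k in range(m):
        cols[:, k] = np.roll(mother, k * block)[:n]
    cols[:, m] = 1.0
    cols[:, m + 1] = np.linspace(-1.0, 1.0, n)
    return cols


def wavelet_detrend(
    signal: np.ndarray, sample_rate: float, stride_period_estimate: float
) -> np.ndarray:
    """Remove trends slower than the stride period (orthogonal projection)."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise DataError("wavelet_detrend expects a 1-D signal")
    if not np.all(np.isfinite(x)):
        raise DataError("non-finite samples")
    n = len(x)
    if n < 4 * stride_period_estimate * sample_rate:
        raise DataError("signal shorter than 4 stride periods")
    level = detrend_level(sample_rate, stride_period_estimate)
    level = min(level, int(np.floor(np.log2(n))) - 1)
    if level < 1:
        raise DataError("signal too short for wavelet decomposition")
    basis = _scaling_basis(n, level)
    coeff, *_ = np.linalg.lstsq(basis, x, rcond=None)
    return x - basis @ coeff


def estimate_stride_period(v_axis: np.ndarray, sample_rate: float) -> float:
    """Stride period from the dominant V-axis spectral peak.

    If the dominant peak lies in the step band (>= 1.4 Hz) it is taken as
    the step frequency and the stride period is twice its inverse.
    """
    x = np.asarray(v_axis, dtype=float)
    nper = min(len(x), int(10 * sample_rate))
    freqs, pxx = welch(x - x.mean(), fs=sample_rate, nperseg=nper)
    band = (freqs >= 0.3) & (freqs <= 4.0)
    if not np.any(band) or pxx[band].max() <= 0:
        raise DataError("cannot estimate stride period: no spectral peak")
    fd = freqs[band][np.argmax(pxx[band])]
    return 2.0 / fd if fd >= 1.4 else 1.0 / fd


def integrate_to_velocity(
    acc: np.ndarray, sample_rate: float, stride_period_estimate: float
) -> VelocitySignal:
    """Cumulative trapezoidal integration per axis + drift removal."""
    acc = np.asarray(acc, dtype=float)
    if not np.all(np.isfinite(acc)):
        raise DataError("non-finite acceleration")
    if acc.ndim == 1:
        acc = acc[:, None]
    vel = cumulative_trapezoid(acc, dx=1.0 / sample_rate, axis=0, initial=0.0)
    out = np.column_stack(
        [
            wavelet_detrend(vel[:, j], sample_rate, stride_period_estimate)
            for j in range(vel.shape[1])
        ]
    )
    return VelocitySignal(out, sample_rate)


@dataclass
class StepDetectionParams:
    min_separation_s: float = 0.25
    prominence_fraction: float = 0.10  # of the v_V standard deviation
    min_height_fraction: float = 0.3  # of the median peak height
    min_steps: int = 10


def detect_steps(v: VelocitySignal, params: StepDetectionParams = None) -> StepSeries:
    """Step onsets as local maxima of the vertical velocity.

    Peaks far below the typical peak height (spurious maxima in the rest
    margins that bout bridging can include) are discarded.
    """
    p = params or StepDetectionParams()
    vv = v.channel("v")
    sd = vv.std()
    if sd == 0:
        raise BoutRejected("constant vertical velocity: no maxima")
    peaks, _ = find_peaks(
        vv,
        distance=max(1, int(round(p.min_separation_s * v.sample_rate))),
        prominence=p.prominence_fraction * sd,
    )
    if len(peaks) >= 3:
        floor = p.min_height_fraction * np.median(vv[peaks])
        peaks = peaks[vv[peaks] >= floor]
    if len(peaks) < p.min_steps:
        raise BoutRejected(f"only {len(peaks)} steps detected (< {p.min_steps})")
    return StepSeries(peaks, v.sample_rate)


def autocorr_step_time(v_axis: np.ndarray, sample_rate: float) -> float:
    """Dominant-period oracle: first autocorrelation peak beyond 0.25 s.

    On the vertical velocity (step-frequency dominated) the first peak sits
    at the step lag; taking the global argmax would return the stride lag.
    """
    x = np.asarray(v_axis, dtype=float)
    x = x - x.mean()
    ac = np.correlate(x, x, mode="full")[len(x) - 1 :]
    lo = int(0.25 * sample_rate)
    hi = min(len(ac) - 1, int(2.0 * sample_rate))
    peaks, _ = find_peaks(ac[lo:hi], prominence=0.05 * ac[0])
    if len(peaks) == 0:
        raise DataError("no autocorrelation peak")
    return (lo + peaks[0]) / sample_rate
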