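"""Conventional gait features of daily-life walking bouts.

Per-axis (AP, ML, V) features: harmonic ratio, step symmetry, step and
stride regularity, acceleration RMS and range, amplitude/width/slope of
the dominant frequency.  Scalar features: cadence, average step and stride
duration, bout-duration and step-count statistics, plus the three per-axis
Wolf exponents and the eight phase-dependent exponents computed elsewhere.

Formulas follow common accelerometry conventions: regularity is the
unbiased normalised autocorrelation at the mean step / stride lag, the
harmonic ratio is the even/odd (ML: odd/even) amplitude ratio over the
first 20 stride harmonics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy.signal import welch

from .core import AXES, DataError, StepSeries

HR_CAP = 10.0

#: the eight phase-dependent discriminant features (matrix X3)
PHASE_LAMBDA_FEATURES = tuple(
    f"lambda_{emb}_p{ph}_eq{eq}"
    for emb in ("diff", "lag")
    for ph in (0, 60)
    for eq in (1, 2)
)

PER_AXIS_FEATURES = (
    "harmonic_ratio",
    "step_symmetry",
    "step_regularity",
    "stride_regularity",
    "rms",
    "range",
    "dom_amplitude",
    "dom_width",
    "dom_slope",
)

SCALAR_FEATURES = (
    "cadence",
    "step_duration",
    "stride_duration",
    "median_bout_duration",
    "median_steps_per_bout",
    "total_steps",
    "total_bouts",
    "pct_walking",
)


def feature_names() -> List[str]:
    """The 46 feature names of the full predictor matrix X1."""
    names = [f"{ax}_{feat}" for feat in PER_AXIS_FEATURES for ax in AXES]
    names += [f"{ax}_lambda_wolf" for ax in AXES]
    names += list(SCALAR_FEATURES)
    names += list(PHASE_LAMBDA_FEATURES)
    return names


def spectral_features(
    x: np.ndarray, sample_rate: float, band=(0.5, 3.0)
) -> Dict[str, float]:
    """Amplitude, width and slope of the dominant frequency (Welch PSD)."""
    x = np.asarray(x, dtype=float)
    nper = min(len(x), int(10 * sample_rate))
    freqs, pxx = welch(x - x.mean(), fs=sample_rate, nperseg=nper)
    total = pxx.sum()
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if total <= 0 or not np.any(in_band):
        return {"dom_frequency": np.nan, "dom_amplitude": np.nan,
                "dom_width": np.nan, "dom_slope": np.nan}
    bi = np.flatnonzero(in_band)
    peak = bi[np.argmax(pxx[bi])]
    amplitude = float(pxx[peak] / total)
    half = 0.5 * pxx[peak]
    left = peak
    while left > 0 and pxx[left - 1] >= half:
        left -= 1
    right = peak
    while right < len(pxx) - 1 and pxx[right + 1] >= half:
        right += 1
    width = float(freqs[right] - freqs[left])
    width = max(width, float(freqs[1] - freqs[0]))  # at least one bin
    return {
        "dom_frequency": float(freqs[peak]),
        "dom_amplitude": amplitude,
        "dom_width": width,
        "dom_slope": amplitude / width,
    }


def _autocorr_at(x: np.ndarray, lag: int) -> float:
    """Unbiased normalised autocorrelation at an integer lag."""
    n = len(x)
    if lag <= 0 or lag >= n:
        return np.nan
    x = x - x.mean()
    var = np.mean(x**2)
    if var == 0:
        return np.nan
    return float(np.sum(x[:-lag] * x[lag:]) / ((n - lag) * var))


def regularity_symmetry(x: np.ndarray, steps: StepSeries) -> Dict[str, float]:
    """Step/stride regularity and step symmetry from the autocorrelation."""
    step_lag = int(round(steps.mean_step_time * steps.sample_rate))
    stride_lag = int(round(steps.mean_stride_time * steps.sample_rate))
    step_reg = _autocorr_at(x, step_lag)
    stride_reg = _autocorr_at(x, stride_lag)
    if np.isfinite(step_reg) and np.isfinite(stride_reg) and stride_reg != 0:
        sym = abs(step_reg) / abs(stride_reg)
        if sym > 1:
            sym = 1.0 / sym
    else:
        sym = np.nan
    return {"step_regularity": step_reg, "stride_regularity": stride_reg,
            "step_symmetry": sym}


def harmonic_amplitudes(
    x: np.ndarray, sample_rate: float, stride_frequency: float, n_harmonics: int = 20
) -> np.ndarray:
    """Finite-Fourier amplitudes at the first ``n_harmonics`` stride harmonics."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    t = np.arange(len(x)) / sample_rate
    k = np.arange(1, n_harmonics + 1)
    basis = np.exp(-2j * np.pi * stride_frequency * np.outer(k, t))
    return 2.0 * np.abs(basis @ x) / len(x)


def harmonic_ratio(
    x: np.ndarray,
    sample_rate: float,
    steps: StepSeries,
    axis: str,
    n_harmonics: int = 20,
    cap: float = HR_CAP,
) -> float:
    """Even/odd stride-harmonic amplitude ratio (odd/even for ML)."""
    stride_t = steps.mean_stride_time
    if not np.isfinite(stride_t) or stride_t <= 0:
        raise DataError("stride frequency unresolved")
    amps = harmonic_amplitudes(x, sample_rate, 1.0 / stride_t, n_harmonics)
    even = amps[1::2].sum()  # harmonics 2, 4, ... (step frequency multiples)
    odd = amps[0::2].sum()  # harmonics 1, 3, ...
    num, den = (odd, even) if axis == "ml" else (even, odd)
    if den == 0:
        return cap
    return float(min(num / den, cap))


def amplitude_features(x: np.ndarray) -> Dict[str, float]:
    x = np.asarray(x, dtype=float)
    c = x - x.mean()
    return {"rms": float(np.sqrt(np.mean(c**2))), "range": float(x.max() - x.min())}


def bout_axis_features(
    acc: np.ndarray, sample_rate: float, steps: StepSeries
) -> Dict[str, float]:
    """All per-axis features for one bout; keys prefixed with the axis."""
    out: Dict[str, float] = {}
    for j, ax in enumerate(AXES):
        x = acc[:, j]
        out.update({f"{ax}_{k}": v for k, v in amplitude_features(x).items()})
        spec = spectral_features(x, sample_rate)
        out.update({f"{ax}_{k}": v for k, v in spec.items() if k != "dom_frequency"})
        out.update({f"{ax}_{k}": v for k, v in regularity_symmetry(x, steps).items()})
        out[f"{ax}_harmonic_ratio"] = harmonic_ratio(x, sample_rate, steps, ax)
    return out


def timing_features(
    bout_durations: Sequence[float],
    bout_step_counts: Sequence[int],
    bout_mean_step_times: Sequence[float],
    bout_mean_stride_times: Sequence[float],
    recording_duration: float,
) -> Dict[str, float]:
    """Recording-level timing/bout statistics."""
    durations = np.asarray(bout_durations, dtype=float)
    counts = np.asarray(bout_step_counts, dtype=float)
    total_walk = durations.sum()
    total_steps = counts.sum()
    mean_step = float(np.nanmean(bout_mean_step_times))
    return {
        # steps/min while actually stepping; derived from the step period so
        # that slack in detected bout boundaries does not bias it
        "cadence": 60.0 / mean_step if mean_step > 0 else np.nan,
        "step_duration": mean_step,
        "stride_duration": float(np.nanmean(bout_mean_stride_times)),
        "median_bout_duration": float(np.median(durations)) if len(durations) else np.nan,
        "median_steps_per_bout": float(np.median(counts)) if len(counts) else np.nan,
        "total_steps": float(total_steps),
        "total_bouts": float(len(durations)),
        "pct_walking": 100.0 * total_walk / recording_duration
        if recording_duration > 0
        else np.nan,
    }


# ---------------------------------------------------------------------------
# cohort assembly


def zscore(df: pd.DataFrame) -> pd.DataFrame:
    mu = df.mean(axis=0)
    sd = df.std(axis=0, ddof=1)
    sd = sd.replace(0.0, 1.0)
    return (df - mu) / sd


def assemble_matrices(
    features: pd.DataFrame, max_missing_fraction: float = 0.3
):
    """Build the z-scored predictor matrices (X1, X2, X3).

    ``features`` is subjects x named features (index = subject_id).
    Subjects missing more than ``max_missing_fraction`` of features are
    dropped; remaining missing entries are imputed with the cohort median.
    """
    names = feature_names()
    missing_cols = [c for c in names if c not in features.columns]
    if missing_cols:
        raise DataError(f"feature matrix lacks columns: {missing_cols[:5]}...")
    X = features[names].astype(float)
    frac_missing = X.isna().mean(axis=1)
    X = X.loc[frac_missing <= max_missing_fraction]
    X = X.fillna(X.median(axis=0))
    X = X.fillna(0.0)  # columns missing for the whole cohort
    x1 = zscore(X)
    phase_cols = list(PHASE_LAMBDA_FEATURES)
    x2 = x1.drop(columns=phase_cols)
    x3 = x1[phase_cols]
    return x1, x2, x3
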