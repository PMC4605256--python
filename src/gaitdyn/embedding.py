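"""6D state-space reconstruction for walking bouts.

Two constructions are provided: differential coordinates (three
acceleration + three velocity channels) and delayed coordinates (the three
velocity channels and a short-lag copy of each).  Columns are z-scored
within the bout before any distance computation, since acceleration and
velocity carry incommensurate units.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import (
    ConfigurationError,
    DataError,
    StateTrajectory,
    StepSeries,
    step_phase_annotation,
)


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def embed_differential(
    acc: np.ndarray,
    vel: np.ndarray,
    steps: StepSeries = None,
    dt: float = 0.01,
    standardize: bool = True,
) -> StateTrajectory:
    """State space [a_AP, a_ML, a_V, v_AP, v_ML, v_V]."""
    acc = np.asarray(acc, dtype=float)
    vel = np.asarray(vel, dtype=float)
    if acc.shape != vel.shape:
        raise DataError("acceleration and velocity must be aligned")
    X = np.column_stack([acc, vel])
    if standardize:
        X = _standardize(X)
    phase = idx = None
    if steps is not None:
        phase, idx = step_phase_annotation(len(X), steps.onsets)
    return StateTrajectory(X, method="diff", dt=dt, lag=0, phase=phase, step_index=idx)


def embed_delayed(
    vel: np.ndarray,
    lag: int = 3,
    steps: StepSeries = None,
    dt: float = 0.01,
    standardize: bool = True,
) -> StateTrajectory:
    """State space [v_AP(t), v_AP(t+l dt), v_ML(t), v_ML(t+l dt), v_V(t), v_V(t+l dt)].

    The point at row ``t`` spans samples ``t .. t+l`` and is annotated with
    the phase of the midpoint sample, centring its phase support.
    """
    vel = np.asarray(vel, dtype=float)
    if lag < 1:
        raise ConfigurationError("lag must be >= 1 (duplicate columns otherwise)")
    n = len(vel)
    if lag >= n:
        raise DataError("lag must be shorter than the signal")
    m = n - lag
    cols = []
    for j in range(3):
        cols.append(vel[:m, j])
        cols.append(vel[lag : lag + m, j])
    X = np.column_stack(cols)
    if standardize:
        X = _standardize(X)
    phase = idx = None
    if steps is not None:
        phase, idx = step_phase_annotation(n, steps.onsets)
        mid = lag // 2
        phase, idx = phase[mid : mid + m], idx[mid : mid + m]
    return StateTrajectory(X, method="lag", dt=dt, lag=lag, phase=phase, step_index=idx)


def delay_embed_univariate(x: np.ndarray, dim: int, lag: int) -> np.ndarray:
    """Plain delay embedding of a scalar series: rows [x(t), x(t+l), ...]."""
    x = np.asarray(x, dtype=float)
    m = len(x) - (dim - 1) * lag
    if m < 1:
        raise DataError("signal too short for requested embedding")
    return np.column_stack([x[j * lag : j * lag + m] for j in range(dim)])


def ami(signal: np.ndarray, lag: int, bins: int = 16) -> float:
    """Average mutual information I(x_t; x_{t+lag}) with equiprobable bins."""
    x = np.asarray(signal, dtype=float)
    if x.std() == 0:
        raise DataError("constant signal: mutual information undefined")
    edges = np.quantile(x, np.linspace(0, 1, bins + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        raise DataError("signal has too few distinct values")
    edges[0] -= 1e-12
    edges[-1] += 1e-12
    a = np.digitize(x[:-lag], edges) - 1
    b = np.digitize(x[lag:], edges) - 1
    nb = len(edges) - 1
    joint = np.zeros((nb, nb))
    np.add.at(joint, (a, b), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz])))


def ami_first_minimum(signal: np.ndarray, max_lag: int = 25, bins: int = 16) -> int:
    """First strict local minimum of the AMI function over lags 1..max_lag.

    Falls back to the argmin (with a warning) when no strict interior
    minimum exists, e.g. for white noise.
    """
    x = np.asarray(signal, dtype=float)
    if len(x) < 10 * max_lag:
        raise DataError("signal too short for AMI lag search")
    vals = np.array([ami(x, tau, bins=bins) for tau in range(1, max_lag + 1)])
    for i in range(1, len(vals) - 1):
        if vals[i] < vals[i - 1] and vals[i] < vals[i + 1]:
            return i + 1
    warnings.warn("no strict AMI minimum found; returning argmin")
    return int(np.argmin(vals)) + 1
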