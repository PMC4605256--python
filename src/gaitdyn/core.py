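"""Shared data structures and errors for the gait-dynamics pipeline.

Conventions used throughout the package:

* acceleration arrays are ``(n_samples, 3)`` with columns ordered
  anterior-posterior (AP), mediolateral (ML), vertical (V);
* index ranges are 0-based and half-open;
* a "step cycle" runs from one detected step onset to the next, and
  within-cycle phase is the elapsed fraction in ``[0, 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

AXES = ("ap", "ml", "v")


class ConfigurationError(ValueError):
    """Raised for invalid parameter combinations."""


class DataError(ValueError):
    """Raised for structurally invalid input data (NaNs, length mismatch...)."""


class BoutRejected(RuntimeError):
    """Raised when a walking bout cannot be analysed; carries the reason."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class TriaxialRecording:
    """Continuous triaxial trunk acceleration at a fixed sample rate."""

    acc: np.ndarray  # (n, 3), columns AP, ML, V
    sample_rate: float
    subject_id: str = ""
    group: Optional[str] = None
    units: str = "m/s^2"

    def __post_init__(self):
        self.acc = np.asarray(self.acc, dtype=float)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise DataError("acceleration must be an (n, 3) array")
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.acc.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def channel(self, axis: str) -> np.ndarray:
        return self.acc[:, AXES.index(axis)]


@dataclass(frozen=True)
class WalkingBout:
    """Half-open sample range of a recording classified as walking."""

    start_index: int
    end_index: int
    sample_rate: float
    recording_id: str = ""

    def __post_init__(self):
        if self.end_index <= self.start_index:
            raise DataError("bout end must be after start")

    @property
    def duration(self) -> float:
        return (self.end_index - self.start_index) / self.sample_rate

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index


@dataclass
class VelocitySignal:
    """Intrastep 3D velocity (m/s), same grid as its source bout."""

    vel: np.ndarray  # (n, 3), columns AP, ML, V
    sample_rate: float

    def __post_init__(self):
        self.vel = np.asarray(self.vel, dtype=float)
        if self.vel.ndim != 2 or self.vel.shape[1] != 3:
            raise DataError("velocity must be an (n, 3) array")
        if not np.all(np.isfinite(self.vel)):
            raise DataError("velocity contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.vel.shape[0]

    def channel(self, axis: str) -> np.ndarray:
        return self.vel[:, AXES.index(axis)]


@dataclass
class StepSeries:
    """Step onsets (sample indices within a bout) and derived timing."""

    onsets: np.ndarray
    sample_rate: float

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=int)
        if np.any(np.diff(self.onsets) <= 0):
            raise DataError("step onsets must be strictly increasing")

    @property
    def n_steps(self) -> int:
        return len(self.onsets)

    @property
    def step_times(self) -> np.ndarray:
        """Durations of individual step cycles (s)."""
        return np.diff(self.onsets) / self.sample_rate

    @property
    def stride_times(self) -> np.ndarray:
        """Durations of strides, i.e. two consecutive steps (s)."""
        if len(self.onsets) < 3:
            return np.empty(0)
        return (self.onsets[2:] - self.onsets[:-2]) / self.sample_rate

    @property
    def mean_step_time(self) -> float:
        return float(np.mean(self.step_times)) if len(self.onsets) > 1 else np.nan

    @property
    def mean_stride_time(self) -> float:
        st = self.stride_times
        return float(np.mean(st)) if len(st) else np.nan


@dataclass
class StateTrajectory:
    """A 6D reconstructed state space trajectory for one walking bout.

    ``points[t]`` is the state at bout sample ``t``; for delayed embeddings
    sample ``t`` combines samples ``t`` and ``t + lag``.  ``phase[t]`` is
    the fraction of the current step cycle elapsed at sample ``t`` (NaN
    outside detected cycles) and ``step_index[t]`` is the 0-based index of
    that cycle (-1 outside).
    """

    points: np.ndarray  # (n_points, 6)
    method: str  # "diff" | "lag" | "wolf"
    dt: float
    lag: int = 0
    phase: np.ndarray = field(default=None)
    step_index: np.ndarray = field(default=None)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2:
            raise DataError("trajectory must be 2-D")
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=float)
            if len(self.phase) != len(self.points):
                raise DataError("phase annotation length mismatch")
        if self.step_index is not None:
            self.step_index = np.asarray(self.step_index, dtype=int)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]


def step_phase_annotation(n_samples: int, onsets: np.ndarray):
    """Per-sample step phase in [0, 1) and step-cycle index.

    Samples before the first onset or at/after the last onset get phase NaN
    and index -1: they do not belong to a complete step cycle.
    """
    onsets = np.asarray(onsets, dtype=int)
    phase = np.full(n_samples, np.nan)
    idx = np.full(n_samples, -1, dtype=int)
    t = np.arange(n_samples)
    which = np.searchsorted(onsets, t, side="right") - 1
    valid = (which >= 0) & (which < len(onsets) - 1)
    w = which[valid]
    dur = (onsets[w + 1] - onsets[w]).astype(float)
    phase[valid] = (t[valid] - onsets[w]) / dur
    idx[valid] = w
    return phase, idx
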