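"""Walking-bout identification in continuous triaxial recordings.

Two moving-window filters are combined: an amplitude filter (standard
deviation of the acceleration vector magnitude) and a frequency-domain
energy filter (fraction of spectral power in the locomotor band).  Windows
passing both filters are merged, short gaps are bridged, and only merged
segments of at least ``min_duration_s`` are kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .core import DataError, TriaxialRecording, WalkingBout

G = 9.80665  # m/s^2 per g


@dataclass
class BoutDetectionParams:
    window_s: float = 5.0
    overlap: float = 0.5
    amplitude_threshold: float = 0.05 * G  # SD of vector magnitude, m/s^2
    locomotor_band: tuple = (0.5, 3.0)  # Hz
    total_band: tuple = (0.0, 10.0)  # Hz
    energy_fraction: float = 0.5
    bridge_gap_s: float = 2.5
    min_duration_s: float = 60.0


def _band_fraction(x: np.ndarray, fs: float, p: BoutDetectionParams) -> float:
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    total = spec[(freqs >= p.total_band[0]) & (freqs <= p.total_band[1])].sum()
    if total <= 0:
        return 0.0
    band = spec[(freqs >= p.locomotor_band[0]) & (freqs <= p.locomotor_band[1])].sum()
    return band / total


def _window_passes(
    mag_seg: np.ndarray, acc_seg: np.ndarray, fs: float, p: BoutDetectionParams
) -> bool:
    # amplitude filter on the vector magnitude; energy filter on the axis
    # with the clearest locomotor-band dominance
    if mag_seg.std() <= p.amplitude_threshold:
        return False
    frac = max(_band_fraction(acc_seg[:, j], fs, p) for j in range(acc_seg.shape[1]))
    return frac > p.energy_fraction


def detect_walking_bouts(
    rec: TriaxialRecording, params: Optional[BoutDetectionParams] = None
) -> List[WalkingBout]:
    """Detect walking bouts of duration >= ``min_duration_s``.

    Returns an empty list for recordings shorter than one window.
    """
    p = params or BoutDetectionParams()
    if not np.all(np.isfinite(rec.acc)):
        raise DataError("recording contains non-finite samples")
    fs = rec.sample_rate
    win = int(round(p.window_s * fs))
    hop = max(1, int(round(win * (1.0 - p.overlap))))
    n = rec.n_samples
    if n < win:
        return []
    mag = np.linalg.norm(rec.acc, axis=1)

    mask = np.zeros(n, dtype=bool)
    for start in range(0, n - win + 1, hop):
        if _window_passes(
            mag[start : start + win], rec.acc[start : start + win], fs, p
        ):
            mask[start : start + win] = True

    # bridge short gaps between passing regions
    bridge = int(round(p.bridge_gap_s * fs))
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8)])) == 1))
    ends = list(np.flatnonzero(np.diff(np.concatenate([mask.view(np.int8), [0]])) == -1) + 1)
    del edges
    merged = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] <= bridge:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    # refine edges with a 1-s amplitude window: the coarse windows can
    # overhang into rest by up to half a window length
    short = int(round(fs))
    step = max(1, short // 10)
    refined = []
    for s, e in merged:
        while s + short < e and mag[s : s + short].std() <= p.amplitude_threshold:
            s += step
        while e - short > s and mag[e - short : e].std() <= p.amplitude_threshold:
            e -= step
        refined.append((s, e))

    min_len = int(round(p.min_duration_s * fs))
    return [
        WalkingBout(s, e, fs, recording_id=rec.subject_id)
        for s, e in refined
        if e - s >= min_len
    ]


def bout_table(bouts: List[WalkingBout]) -> pd.DataFrame:
    """Bout table (subject_id, bout_idx, start_s, end_s) for CSV export."""
    rows = [
        {
            "subject_id": b.recording_id,
            "bout_idx": i,
            "start_s": b.start_index / b.sample_rate,
            "end_s": b.end_index / b.sample_rate,
        }
        for i, b in enumerate(bouts)
    ]
    return pd.DataFrame(rows, columns=["subject_id", "bout_idx", "start_s", "end_s"])


def read_recording(path, sample_rate: Optional[float] = None) -> TriaxialRecording:
    """Read a columnar text recording (time_s, acc_AP, acc_ML, acc_V).

    Tolerates an optional header line.  The sample rate is inferred from
    the time column unless given explicitly.
    """
    path = Path(path)
    data = np.genfromtxt(path, delimiter=",", names=True)
    if data.dtype.names is None or "time_s" not in data.dtype.names:
        raw = np.loadtxt(path, delimiter=",")
        t, acc = raw[:, 0], raw[:, 1:4]
    else:
        t = data["time_s"]
        acc = np.column_stack([data["acc_AP"], data["acc_ML"], data["acc_V"]])
    if sample_rate is None:
        dt = np.median(np.diff(t))
        if dt <= 0:
            raise DataError("non-increasing time column")
        sample_rate = 1.0 / dt
    return TriaxialRecording(acc, float(sample_rate), subject_id=path.stem)
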