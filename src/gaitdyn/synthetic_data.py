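"""Synthetic daily-life trunk-accelerometry cohorts with known ground truth.

The generator produces multi-bout triaxial recordings with a quasi-periodic
step-cycle structure and a *phase-dependent* perturbation process:

* the noise-free gait signal is a fixed two-harmonic-per-axis waveform over
  the stride cycle (vertical dominated by the step frequency, ML by the
  stride frequency);
* at each of the five control phases (0, 20, 40, 60, 80 % of the step
  cycle) a scalar deviation follows a step-to-step AR(1) process
  ``d_{k+1} = a_p d_k + eps_k`` with ``a_p = exp(contraction_p)``;
* within a step the deviation injected at phase ``p`` is rendered as a
  local *timing* (shape) modulation of a quadrature carrier pair at the
  stride frequency (a sine on AP, a cosine on ML): the carrier phase is
  shifted by ``d_k * exp(contraction_p * (phi - p))``, confined to a
  smooth window around ``p``.  Because the carrier pair traces a circle
  in the (AP, ML) plane, the state-space distance between two
  same-parity step cycles is proportional to their phase-shift
  difference at every point of the cycle, so log-distances between
  neighbouring cycles shrink with slope ``contraction_p`` (per
  step-normalised time) right after ``p`` — an analytically known
  analogue of phase-dependent local dynamic stability.  The carrier is
  rendered with its phase-slew chain-rule factor, so the velocity
  obtained by integrating the acceleration carries the same decaying
  perturbation: both state-space constructions see it.  (Opposite-parity
  cycles sit half a carrier turn apart and never enter a neighbourhood,
  mirroring left/right asymmetry.)  The vertical axis is left
  unmodulated so step detection (vertical-velocity maxima) stays
  accurate.

Innovations are scaled so the *stationary* deviation amplitude equals
``dynamical_noise_sd`` regardless of ``a_p``; groups configured with
different contraction rates then differ in their perturbation dynamics but
not in overall signal amplitude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .core import ConfigurationError, TriaxialRecording

CONTROL_PHASES = np.array([0.0, 0.2, 0.4, 0.6, 0.8])

GROUPS = ("faller", "nonfaller")

#: amplitude of the phase-modulated quadrature carrier (AP sine, ML cosine
#: at the stride frequency); its gradient wrt step phase is pi*CARRIER_AMP,
#: which converts ``dynamical_noise_sd`` into a timing-perturbation scale
CARRIER_AMP = 1.3

# deviation window geometry, in step-phase units relative to the control
# phase: ramp up over [-0.06, -0.03], hold at 1 over [-0.03, +0.13], ramp
# down over [+0.13, +0.19].  The exponent-fit interval [p, p+0.1] sits
# inside the flat region with margin for the phase support of delayed
# embedding states, and the next window's ramp-in (at +0.14) stays clear.
_RAMP_IN_LO = -0.06
_RAMP_IN_HI = -0.03
_FLAT_HI = 0.13
_RAMP_OUT_HI = 0.19


def _default_contraction() -> Dict[str, Tuple[float, ...]]:
    # groups differ only at phases 0% and 60%
    return {
        "faller": (-1.2, -0.3, -0.3, -1.2, -0.3),
        "nonfaller": (-0.02, -0.3, -0.3, -0.02, -0.3),
    }


@dataclass
class GaitSimConfig:
    """Parameters for a synthetic cohort.

    ``phase_contraction`` maps group name to the log contraction rate at
    each of the five control phases; values ``< 0`` mean perturbations
    decay (locally stable), ``0`` means they persist.
    """

    sample_rate: float = 100.0
    n_subjects_per_group: int = 5
    group_sizes: Optional[Dict[str, int]] = None
    bouts_per_subject: int = 5
    bout_count_jitter: int = 2  # per-subject bout count varies by +/- this
    bout_duration: float = 60.0
    bout_duration_jitter: float = 30.0  # bout durations ~ U[d, d + jitter]
    step_frequency_mean: float = 2.0
    step_frequency_cv: float = 0.03
    phase_contraction: Dict[str, Tuple[float, ...]] = field(
        default_factory=_default_contraction
    )
    contraction_subject_sd: float = 0.1
    subject_freq_sd: float = 0.05  # Hz, between-subject step-frequency spread
    subject_amp_sd: float = 0.05  # relative between-subject amplitude spread
    subject_cv_sd: float = 0.015  # between-subject spread of the timing CV
    #: step-to-step AR(1) coefficients per phase; ``None`` couples them to
    #: the within-cycle decay (``exp(phase_contraction)``).  Setting a
    #: common value isolates the within-cycle decay as the only group
    #: difference, which no step-to-step autocorrelation feature can see.
    ar_persistence: Optional[Tuple[float, ...]] = None
    dynamical_noise_sd: float = 0.25
    measurement_noise_sd: float = 0.02
    rest_gap_duration: float = 20.0
    rest_noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")
        if self.bout_duration < 60.0:
            raise ConfigurationError("bout_duration must be >= 60 s")
        if self.step_frequency_mean <= 0:
            raise ConfigurationError("step_frequency_mean must be positive")
        if self.bouts_per_subject < 1:
            raise ConfigurationError("bouts_per_subject must be >= 1")
        if self.rest_gap_duration <= 0:
            raise ConfigurationError("rest_gap_duration must be positive")
        if self.dynamical_noise_sd < 0 or self.measurement_noise_sd < 0:
            raise ConfigurationError("noise SDs must be non-negative")
        for g, rates in self.phase_contraction.items():
            rates = np.asarray(rates, dtype=float)
            if rates.shape != (5,) or not np.all(np.isfinite(rates)):
                raise ConfigurationError(
                    f"phase_contraction[{g!r}] must be 5 finite values"
                )

    def sizes(self) -> Dict[str, int]:
        if self.group_sizes is not None:
            return dict(self.group_sizes)
        return {g: self.n_subjects_per_group for g in GROUPS}


@dataclass
class BoutTruth:
    """Ground truth for one walking bout."""

    start_index: int
    end_index: int
    step_onset_times: np.ndarray  # seconds, relative to recording start
    deviations: np.ndarray  # (n_steps, 5) AR(1) deviation series per phase


@dataclass
class GroundTruth:
    """Ground truth for one simulated subject."""

    subject_id: str
    group: str
    contraction: np.ndarray  # (5,) true per-phase log contraction rate
    bouts: list

    def bout_schedule(self) -> np.ndarray:
        return np.array([[b.start_index, b.end_index] for b in self.bouts])


def stride_template(phi_stride: np.ndarray) -> np.ndarray:
    """Noise-free acceleration waveform (AP, ML, V) vs stride phase in [0, 1).

    Harmonic content: V is dominated by the second stride harmonic (the
    step frequency) and ML by the first (the stride frequency), so
    harmonic-ratio features behave directionally as in real gait; AP
    mirrors ML's per-frequency power so the carrier plane stays isotropic
    under per-column standardisation.
    """
    phi = np.asarray(phi_stride, dtype=float)
    ap, ml = _template_apml(phi)
    car_ap, car_ml = _carrier(phi)
    return np.stack([ap + car_ap, ml + car_ml, _template_v(phi)], axis=-1)


def _template_apml(phi):
    # AP and ML carry identical per-frequency power and are in quadrature
    # with the carrier, so per-column standardisation leaves the carrier
    # plane isotropic (in acceleration and, frequency-wise, in velocity)
    ap = 0.3 * np.sin(4 * np.pi * phi + 1.0) + 1.6 * np.cos(2 * np.pi * phi)
    ml = 0.3 * np.sin(4 * np.pi * phi + 0.8) + 1.6 * np.sin(2 * np.pi * phi)
    return ap, ml


def _carrier(phi_stride):
    """Quadrature carrier at the stride frequency; hosts timing deviations."""
    return (
        CARRIER_AMP * np.sin(2 * np.pi * phi_stride),
        CARRIER_AMP * np.cos(2 * np.pi * phi_stride),
    )


def _template_v(phi):
    # signs chosen so the integral (vertical velocity) peaks at step onsets,
    # aligning detected onsets with the generator's nominal step starts
    return -2.4 * np.sin(4 * np.pi * phi) - 0.5 * np.sin(2 * np.pi * phi)


def _deviation_window(tau: np.ndarray) -> np.ndarray:
    """Smooth activation of a phase-local deviation, as a function of
    step-phase offset ``tau`` from the control phase."""
    w = np.zeros_like(tau)
    rise = (tau >= _RAMP_IN_LO) & (tau < _RAMP_IN_HI)
    w[rise] = 0.5 * (
        1 - np.cos(np.pi * (tau[rise] - _RAMP_IN_LO) / (_RAMP_IN_HI - _RAMP_IN_LO))
    )
    w[(tau >= _RAMP_IN_HI) & (tau <= _FLAT_HI)] = 1.0
    fall = (tau > _FLAT_HI) & (tau <= _RAMP_OUT_HI)
    w[fall] = 0.5 * (
        1 + np.cos(np.pi * (tau[fall] - _FLAT_HI) / (_RAMP_OUT_HI - _FLAT_HI))
    )
    return w


def _simulate_bout(
    rng,
    cfg: GaitSimConfig,
    contraction: np.ndarray,
    step_frequency: float = None,
    amp_scale: np.ndarray = None,
    timing_cv: float = None,
    ar_coeff: np.ndarray = None,
    bout_duration: float = None,
):
    """One walking bout: acceleration (n, 3), step-onset times (s), deviations."""
    fs = cfg.sample_rate
    f = step_frequency if step_frequency is not None else cfg.step_frequency_mean
    cv = timing_cv if timing_cv is not None else cfg.step_frequency_cv
    target = bout_duration if bout_duration is not None else cfg.bout_duration
    durations = []
    total = 0.0
    while total < target:
        T = (1.0 / f) * (1.0 + cv * rng.standard_normal())
        T = max(T, 0.4 / f)
        durations.append(T)
        total += T
    durations = np.array(durations)
    n_steps = len(durations)
    onset_times = np.concatenate([[0.0], np.cumsum(durations)])

    if ar_coeff is not None:
        a = np.asarray(ar_coeff, dtype=float)
    else:
        a = np.exp(contraction)
    # innovations scaled for stationary SD == dynamical_noise_sd
    innov_sd = cfg.dynamical_noise_sd * np.sqrt(np.clip(1.0 - a**2, 1e-4, None))
    dev = np.empty((n_steps, 5))
    d = rng.standard_normal(5) * cfg.dynamical_noise_sd
    for k in range(n_steps):
        dev[k] = d
        d = a * d + innov_sd * rng.standard_normal(5)

    n_samples = int(round(onset_times[-1] * fs))
    t = np.arange(n_samples) / fs
    step_idx = np.clip(np.searchsorted(onset_times, t, side="right") - 1, 0, n_steps - 1)
    phi_step = (t - onset_times[step_idx]) / durations[step_idx]

    # timing-perturbation field (step-phase units) from the AR(1) deviations
    eps_scale = 1.0 / (np.pi * CARRIER_AMP)
    dphi = np.zeros(n_samples)
    for j, p in enumerate(CONTROL_PHASES):
        tau = phi_step - p
        w = _deviation_window(tau)
        active = w > 0
        if np.any(active):
            decay = np.exp(contraction[j] * np.clip(tau[active], 0.0, None))
            dphi[active] += dev[step_idx[active], j] * eps_scale * decay * w[active]
        if p == 0.0:
            # ramp-in of the phase-0 deviation reaches into the previous
            # step's tail (no discontinuity at the step boundary)
            tau_w = phi_step - 1.0
            w_w = _deviation_window(tau_w)
            act = w_w > 0
            if np.any(act):
                nxt = np.minimum(step_idx[act] + 1, n_steps - 1)
                dphi[act] += dev[nxt, j] * eps_scale * w_w[act]

    phi_stride = ((step_idx % 2) + phi_step) / 2.0
    ap, ml = _template_apml(phi_stride)
    car_ap, car_ml = _carrier(phi_stride + dphi / 2.0)
    # chain-rule factor: with it the time-integral of the carrier equals the
    # phase-shifted carrier antiderivative, so the velocity channels carry
    # the same decaying timing perturbation as the acceleration channels
    jac = 1.0 + np.gradient(dphi) * fs * durations[step_idx]
    acc = np.stack(
        [ap + car_ap * jac, ml + car_ml * jac, _template_v(phi_stride)], axis=-1
    )
    if amp_scale is not None:
        acc = acc * amp_scale[None, :]
    return acc, onset_times[:-1], dev


def simulate_subject(
    cfg: GaitSimConfig, subject_id: str, group: str, subject_index: int = 0
) -> Tuple[TriaxialRecording, GroundTruth]:
    """Simulate one subject's multi-bout recording plus its ground truth."""
    if group not in cfg.phase_contraction:
        raise ConfigurationError(f"unknown group {group!r}")
    rng = np.random.default_rng(
        [cfg.seed, GROUPS.index(group) if group in GROUPS else 97, subject_index]
    )
    contraction = np.asarray(cfg.phase_contraction[group], dtype=float).copy()
    if cfg.contraction_subject_sd > 0:
        contraction = contraction + cfg.contraction_subject_sd * rng.standard_normal(5)
    if cfg.ar_persistence is None:
        # AR coefficient is exp(contraction): keep the process stable
        contraction = np.minimum(contraction, -1e-3)
    else:
        # decoupled persistence: mild local instability is allowed
        contraction = np.minimum(contraction, 1.0)
    f_subj = cfg.step_frequency_mean + cfg.subject_freq_sd * rng.standard_normal()
    f_subj = max(f_subj, 0.5 * cfg.step_frequency_mean)
    # one shared AP/ML scale (keeps the carrier plane isotropic) + a V scale
    s_apml, s_v = 1.0 + cfg.subject_amp_sd * rng.standard_normal(2)
    amp_subj = np.clip(np.array([s_apml, s_apml, s_v]), 0.5, 1.5)
    cv_subj = float(
        np.clip(cfg.step_frequency_cv + cfg.subject_cv_sd * rng.standard_normal(), 0.0, 0.08)
    )

    fs = cfg.sample_rate
    gap = int(round(cfg.rest_gap_duration * fs))
    chunks = [rng.standard_normal((gap, 3)) * cfg.rest_noise_sd]
    pos = gap
    bouts = []
    n_bouts = cfg.bouts_per_subject
    if cfg.bout_count_jitter > 0:
        n_bouts += int(rng.integers(-cfg.bout_count_jitter, cfg.bout_count_jitter + 1))
        n_bouts = max(n_bouts, 1)
    for _ in range(n_bouts):
        dur = cfg.bout_duration + cfg.bout_duration_jitter * rng.random()
        acc, onsets_s, dev = _simulate_bout(
            rng,
            cfg,
            contraction,
            step_frequency=f_subj,
            amp_scale=amp_subj,
            timing_cv=cv_subj,
            ar_coeff=cfg.ar_persistence,
            bout_duration=dur,
        )
        start = pos
        end = pos + len(acc)
        bouts.append(
            BoutTruth(
                start_index=start,
                end_index=end,
                step_onset_times=onsets_s + start / fs,
                deviations=dev,
            )
        )
        chunks.append(acc)
        chunks.append(rng.standard_normal((gap, 3)) * cfg.rest_noise_sd)
        pos = end + gap
    full = np.concatenate(chunks, axis=0)
    if cfg.measurement_noise_sd > 0:
        full = full + rng.standard_normal(full.shape) * cfg.measurement_noise_sd
    rec = TriaxialRecording(full, fs, subject_id=subject_id, group=group)
    truth = GroundTruth(
        subject_id=subject_id, group=group, contraction=contraction, bouts=bouts
    )
    return rec, truth


def simulate_cohort(cfg: GaitSimConfig):
    """Simulate a full cohort.

    Returns ``(recordings, manifest, truths)`` where manifest is a
    DataFrame with columns ``subject_id`` and ``group``.
    """
    sizes = cfg.sizes()
    if sum(sizes.values()) < 2 or len(sizes) < 1:
        raise ConfigurationError("need at least 2 subjects")
    recordings, truths, rows = [], [], []
    for group, n in sizes.items():
        for i in range(n):
            sid = f"{group[:2].upper()}{i + 1:03d}"
            rec, truth = simulate_subject(cfg, sid, group, subject_index=i)
            recordings.append(rec)
            truths.append(truth)
            rows.append({"subject_id": sid, "group": group})
    manifest = pd.DataFrame(rows)
    return recordings, manifest, truths


# ---------------------------------------------------------------------------
# disk interchange (columnar text + JSON sidecar + CSV manifest)

def write_recording(rec: TriaxialRecording, path) -> None:
    t = rec.time
    data = np.column_stack([t, rec.acc])
    header = "time_s,acc_AP,acc_ML,acc_V"
    np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.6f")


def write_ground_truth(truth: GroundTruth, path) -> None:
    obj = {
        "subject_id": truth.subject_id,
        "group": truth.group,
        "contraction": truth.contraction.tolist(),
        "bouts": [
            {
                "start_index": int(b.start_index),
                "end_index": int(b.end_index),
                "step_onset_times": np.asarray(b.step_onset_times).tolist(),
                "deviations": np.asarray(b.deviations).tolist(),
            }
            for b in truth.bouts
        ],
    }
    Path(path).write_text(json.dumps(obj))


def read_ground_truth(path) -> GroundTruth:
    obj = json.loads(Path(path).read_text())
    return GroundTruth(
        subject_id=obj["subject_id"],
        group=obj["group"],
        contraction=np.asarray(obj["contraction"]),
        bouts=[
            BoutTruth(
                start_index=b["start_index"],
                end_index=b["end_index"],
                step_onset_times=np.asarray(b["step_onset_times"]),
                deviations=np.asarray(b["deviations"]),
            )
            for b in obj["bouts"]
        ],
    )


def write_cohort(cfg: GaitSimConfig, outdir) -> pd.DataFrame:
    """Simulate and write a cohort to ``outdir``; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    recordings, manifest, truths = simulate_cohort(cfg)
    files = []
    for rec, truth in zip(recordings, truths):
        fname = f"{rec.subject_id}.csv"
        write_recording(rec, outdir / fname)
        write_ground_truth(truth, outdir / f"{rec.subject_id}.truth.json")
        files.append(fname)
    manifest = manifest.assign(file=files)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
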