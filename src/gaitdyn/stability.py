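"""Phase-dependent local dynamic stability and Wolf's exponent.

For each step cycle a reference point is taken at the requested phase of
the cycle.  The neighbourhood trajectories are the other cycles of the
bout, each represented by its point at the same phase (within a
tolerance); cycles whose point falls inside the neighbourhood radius and
outside a Theiler window are neighbours.  Each neighbour is traced forward
in time to the start of the next step and the distances are averaged
across neighbours and then across cycles, yielding the reaction curve
<d_i(t)> on a step-normalised time grid.  Two exponents are derived from the log reaction curve:

* ``lambda_eq1`` — OLS slope over the first 10 % of the step cycle;
* ``lambda_eq2`` — log-ratio ``ln(<d(t_n)>/<d(0)>) / t_n`` with
  ``t_n = 0.1`` (step-normalised).

References with fewer than ``min_neighbors`` neighbours or with an
instantaneous cycle time outside the 5-95 percentiles are excluded and
tallied.

``wolf_lambda`` implements the classical trajectory-tracking estimator on
a univariate delay embedding (default: dimension 6, lag 8 samples).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from .core import BoutRejected, DataError, StateTrajectory, StepSeries
from .embedding import delay_embed_univariate

PHASES = (0.0, 0.2, 0.4, 0.6, 0.8)
#: phases entering the discriminant feature set
FEATURE_PHASES = (0.0, 0.6)

_DIST_FLOOR = 1e-10


@dataclass
class StabilityParams:
    radius_factor: float = 0.2  # x RMS distance from the trajectory centroid
    phase_tolerance: float = 0.05  # fraction of the step cycle
    theiler_strides: int = 1
    min_neighbors: int = 10
    max_neighbors: int = 50
    grid_points: int = 101  # per full step cycle
    fit_fraction: float = 0.1
    stride_time_percentiles: tuple = (5.0, 95.0)


@dataclass
class ReactionCurve:
    """Mean log perturbation-reaction distance vs step-normalised time."""

    phase: float
    grid: np.ndarray  # normalised time points, grid[0] == phase
    log_mean_distance: np.ndarray
    n_refs_total: int
    n_refs_used: int
    excluded_fraction: float
    mean_neighbor_count: float

    def initial_distance(self) -> float:
        return float(np.exp(self.log_mean_distance[0]))


def _circular_phase_distance(phase: np.ndarray, p: float) -> np.ndarray:
    d = np.abs(phase - p)
    return np.minimum(d, 1.0 - d)


def reaction_curve(
    traj: StateTrajectory,
    steps: StepSeries,
    phase: float,
    params: Optional[StabilityParams] = None,
) -> ReactionCurve:
    """Reaction curve of perturbations introduced at ``phase`` of the step cycle."""
    prm = params or StabilityParams()
    if traj.phase is None or traj.step_index is None:
        raise DataError("trajectory lacks phase annotation")
    X = traj.points
    n_pts = len(X)
    onsets = steps.onsets[steps.onsets < n_pts]
    n_cycles = len(onsets) - 1
    if n_cycles < 10:
        raise BoutRejected("fewer than 10 complete step cycles")

    cycle_times = np.diff(onsets) / steps.sample_rate
    lo, hi = np.percentile(cycle_times, prm.stride_time_percentiles)

    centroid = X.mean(axis=0)
    rms_extent = np.sqrt(np.mean(np.sum((X - centroid) ** 2, axis=1)))
    radius = prm.radius_factor * rms_extent

    # one candidate point per cycle: the sample at the requested phase
    durs = np.diff(onsets)
    pts = onsets[:-1] + np.minimum(np.round(phase * durs).astype(int), durs - 1)
    phase_ok = _circular_phase_distance(traj.phase[pts], phase) <= prm.phase_tolerance

    grid_all = np.arange(prm.grid_points) / (prm.grid_points - 1)
    grid = grid_all[grid_all >= phase - 1e-9]
    acc_sum = np.zeros(len(grid))
    used = 0
    excluded = 0
    neighbor_counts = []
    cycles = np.arange(n_cycles)

    dist0 = np.linalg.norm(X[pts][:, None, :] - X[pts][None, :, :], axis=2)
    for k in range(n_cycles):
        if not (lo <= cycle_times[k] <= hi):
            excluded += 1
            continue
        ref = pts[k]
        L = onsets[k + 1] - ref
        sel = (
            (np.abs(cycles - k) > prm.theiler_strides)
            & (dist0[k] <= radius)
            & (dist0[k] > _DIST_FLOOR)
            & (pts + L <= n_pts)
            & phase_ok
        )
        n_nb = int(sel.sum())
        if n_nb < prm.min_neighbors:
            excluded += 1
            continue
        nb = pts[sel]
        if n_nb > prm.max_neighbors:
            order = np.argsort(dist0[k][sel])[: prm.max_neighbors]
            nb = nb[order]
            n_nb = prm.max_neighbors
        idx = nb[:, None] + np.arange(L)[None, :]
        D = np.linalg.norm(X[idx] - X[ref : ref + L][None, :, :], axis=2)
        curve = D.mean(axis=0)
        tnorm = phase + np.arange(L) / durs[k]
        acc_sum += np.interp(grid, tnorm, curve)
        used += 1
        neighbor_counts.append(n_nb)

    if used == 0:
        raise BoutRejected(
            "no reference point survived the neighbour/stride-time exclusions"
        )
    mean_curve = acc_sum / used
    return ReactionCurve(
        phase=phase,
        grid=grid,
        log_mean_distance=np.log(np.maximum(mean_curve, _DIST_FLOOR)),
        n_refs_total=n_cycles,
        n_refs_used=used,
        excluded_fraction=excluded / n_cycles,
        mean_neighbor_count=float(np.mean(neighbor_counts)),
    )


def lambda_eq1(curve: ReactionCurve, fit_fraction: float = 0.1) -> float:
    """OLS slope of the log reaction curve over the first 10 % of the cycle."""
    m = curve.grid <= curve.phase + fit_fraction + 1e-9
    t = curve.grid[m]
    y = curve.log_mean_distance[m]
    ok = np.isfinite(y)
    if ok.sum() < 3:
        return np.nan
    t, y = t[ok], y[ok]
    tbar, ybar = t.mean(), y.mean()
    denom = np.sum((t - tbar) ** 2)
    if denom == 0:
        return np.nan
    return float(np.sum((t - tbar) * (y - ybar)) / denom)


def lambda_eq2(curve: ReactionCurve, t_n: float = 0.1) -> float:
    """Log-ratio exponent: (1/t_n) ln(<d(t_n)>/<d(0)>), step-normalised."""
    y0 = curve.log_mean_distance[0]
    yn = np.interp(curve.phase + t_n, curve.grid, curve.log_mean_distance)
    if not (np.isfinite(y0) and np.isfinite(yn)):
        return np.nan
    return float((yn - y0) / t_n)


def subject_lambda(per_bout_values: Sequence[float]) -> float:
    """Per-subject median across bouts, ignoring missing bout values."""
    vals = np.asarray(list(per_bout_values), dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        return np.nan
    return float(np.median(vals))


def compute_bout_lambdas(
    traj_diff: StateTrajectory,
    traj_lag: StateTrajectory,
    steps: StepSeries,
    params: Optional[StabilityParams] = None,
    phases: Sequence[float] = PHASES,
) -> Dict[str, float]:
    """All phase-dependent exponents for one bout.

    Keys are ``lambda_{emb}_p{phase%}_eq{1,2}``; failed phases yield NaN.
    Also returns ``excluded_fraction_{emb}`` diagnostics (max over phases).
    """
    prm = params or StabilityParams()
    out: Dict[str, float] = {}
    for emb, traj in (("diff", traj_diff), ("lag", traj_lag)):
        excl = []
        for p in phases:
            key = f"p{int(round(p * 100))}"
            try:
                curve = reaction_curve(traj, steps, p, prm)
                out[f"lambda_{emb}_{key}_eq1"] = lambda_eq1(curve, prm.fit_fraction)
                out[f"lambda_{emb}_{key}_eq2"] = lambda_eq2(curve, prm.fit_fraction)
                excl.append(curve.excluded_fraction)
            except BoutRejected:
                out[f"lambda_{emb}_{key}_eq1"] = np.nan
                out[f"lambda_{emb}_{key}_eq2"] = np.nan
        out[f"excluded_fraction_{emb}"] = float(np.max(excl)) if excl else np.nan
    return out


# ---------------------------------------------------------------------------
# Wolf's phase-independent exponent


@dataclass
class WolfParams:
    dim: int = 6
    lag: int = 8  # samples; mean first AMI minimum for these signals
    evolve_s: float = 0.03
    theiler_s: float = 1.0
    angle_max_deg: float = 30.0
    max_scale_fraction: float = 0.02  # of the attractor RMS extent


def wolf_lambda(
    x: np.ndarray, sample_rate: float, params: Optional[WolfParams] = None
) -> float:
    """Largest Lyapunov exponent (1/s) by Wolf's trajectory-tracking method.

    The fiducial trajectory's nearest neighbour is evolved alongside it;
    the log separation growth is accumulated over short evolution steps
    and the neighbour is replaced — by the nearest point within a 30-degree
    cone around the current separation vector — whenever the separation
    exceeds ``max_scale_fraction`` of the attractor extent.
    """
    p = params or WolfParams()
    x = np.asarray(x, dtype=float)
    if len(x) < (p.dim - 1) * p.lag + 100:
        raise DataError("signal too short for Wolf's method")
    Y = delay_embed_univariate(x, p.dim, p.lag)
    n = len(Y)
    evolve = max(1, int(round(p.evolve_s * sample_rate)))
    theiler = max(1, int(round(p.theiler_s * sample_rate)))
    extent = np.sqrt(np.mean(np.sum((Y - Y.mean(axis=0)) ** 2, axis=1)))
    scalmx = p.max_scale_fraction * extent
    cos_max = np.cos(np.deg2rad(p.angle_max_deg))
    t_idx = np.arange(n)

    def nearest(i):
        d = np.linalg.norm(Y - Y[i], axis=1)
        ok = (np.abs(t_idx - i) > theiler) & (t_idx + evolve < n) & (d > _DIST_FLOOR)
        if not np.any(ok):
            return None
        return int(np.argmin(np.where(ok, d, np.inf)))

    i = 0
    j = nearest(i)
    if j is None:
        raise DataError("no valid initial neighbour")
    total_log = 0.0
    total_time = 0.0
    while i + evolve < n and j + evolve < n:
        d0 = np.linalg.norm(Y[i] - Y[j])
        i2, j2 = i + evolve, j + evolve
        d1 = np.linalg.norm(Y[i2] - Y[j2])
        if d0 > _DIST_FLOOR and d1 > _DIST_FLOOR:
            total_log += np.log(d1 / d0)
            total_time += evolve / sample_rate
        i = i2
        if i + evolve >= n:
            break
        if d1 <= scalmx:
            j = j2
            continue
        # separation too large: replace, preferring orientation preservation
        diffs = Y - Y[i]
        dist = np.linalg.norm(diffs, axis=1)
        vref = Y[j2] - Y[i]
        nref = np.linalg.norm(vref)
        eligible = (
            (np.abs(t_idx - i) > theiler) & (t_idx + evolve < n) & (dist > _DIST_FLOOR)
        )
        j_new = None
        if nref > _DIST_FLOOR:
            with np.errstate(invalid="ignore", divide="ignore"):
                cosang = (diffs @ vref) / (dist * nref)
            good = eligible & (cosang >= cos_max) & (dist < d1)
            if np.any(good):
                j_new = int(np.argmin(np.where(good, dist, np.inf)))
        if j_new is None:
            j_new = nearest(i)
            if j_new is None:
                break
        j = j_new
    if total_time == 0:
        raise DataError("Wolf's method accumulated no divergence intervals")
    return float(total_log / total_time)
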