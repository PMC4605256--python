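import numpy as np
import pytest

from gaitdyn.core import BoutRejected, DataError, StateTrajectory, StepSeries, step_phase_annotation
from gaitdyn.stability import (
    ReactionCurve,
    StabilityParams,
    WolfParams,
    compute_bout_lambdas,
    lambda_eq1,
    lambda_eq2,
    reaction_curve,
    subject_lambda,
    wolf_lambda,
)
from gaitdyn.synthetic_data import GaitSimConfig, simulate_subject


def make_curve(phase, values, grid=None):
    grid = np.linspace(phase, 1.0, len(values)) if grid is None else grid
    return ReactionCurve(
        phase=phase,
        grid=grid,
        log_mean_distance=np.asarray(values, dtype=float),
        n_refs_total=10,
        n_refs_used=10,
        excluded_fraction=0.0,
        mean_neighbor_count=20.0,
    )


class TestLambdaEq1:
    def test_exact_line(self):
        grid = np.linspace(0.0, 1.0, 101)
        curve = make_curve(0.0, -2.0 + 5.0 * grid, grid)
        assert lambda_eq1(curve) == pytest.approx(5.0, abs=1e-12)

    def test_constant_curve(self):
        curve = make_curve(0.0, np.full(101, -1.3))
        assert lambda_eq1(curve) == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_ols(self, rng):
        grid = np.linspace(0.2, 1.0, 81)
        y = rng.standard_normal(81)
        curve = make_curve(0.2, y, grid)
        m = grid <= 0.2 + 0.1 + 1e-9
        t, yy = grid[m], y[m]
        oracle = np.sum((t - t.mean()) * (yy - yy.mean())) / np.sum((t - t.mean()) ** 2)
        assert lambda_eq1(curve) == pytest.approx(oracle, abs=1e-12)

    def test_insufficient_points(self):
        curve = make_curve(0.0, [1.0, 2.0], np.array([0.0, 0.5]))
        assert np.isnan(lambda_eq1(curve))


class TestLambdaEq2:
    def test_no_divergence(self):
        curve = make_curve(0.0, np.full(101, 0.7))
        assert lambda_eq2(curve) == pytest.approx(0.0, abs=1e-12)

    def test_e_fold_in_tenth_cycle(self):
        grid = np.linspace(0.0, 1.0, 101)
        vals = np.interp(grid, [0.0, 0.1, 1.0], [np.log(0.1), np.log(0.1) + 1, np.log(0.1) + 1])
        curve = make_curve(0.0, vals, grid)
        assert lambda_eq2(curve) == pytest.approx(10.0, rel=1e-9)

    def test_exponential_curve_agrees_with_eq1(self):
        lam = -3.7
        grid = np.linspace(0.6, 1.0, 41)
        curve = make_curve(0.6, np.log(0.2) + lam * (grid - 0.6), grid)
        assert lambda_eq2(curve) == pytest.approx(lambda_eq1(curve), abs=1e-9)
        assert lambda_eq2(curve) == pytest.approx(lam, rel=1e-9)


class TestSubjectLambda:
    def test_median_robust(self):
        assert subject_lambda([1.0, 2.0, 100.0]) == 2.0

    def test_single_bout(self):
        assert subject_lambda([3.2]) == 3.2

    def test_ignores_nan(self):
        assert subject_lambda([np.nan, 4.0, np.nan]) == 4.0

    def test_all_missing(self):
        assert np.isnan(subject_lambda([np.nan, np.nan]))


def _toy_trajectory(rng, n_cycles=20, dur=50):
    """Small annotated trajectory with known cycle structure."""
    n = n_cycles * dur + 1
    onsets = np.arange(0, n, dur)
    X = rng.standard_normal((n, 6)) * 0.1
    phi = 2 * np.pi * np.arange(n) / dur
    X[:, 0] += np.sin(phi)
    X[:, 1] += np.cos(phi)
    phase, idx = step_phase_annotation(n, onsets)
    traj = StateTrajectory(X, "diff", 0.01, phase=phase, step_index=idx)
    steps = StepSeries(onsets, 100.0)
    return traj, steps


class TestReactionCurve:
    def test_degenerate_noise_free_bout_rejected(self):
        # all cycles identical -> all candidate distances are exactly zero
        n_cycles, dur = 30, 50
        n = n_cycles * dur + 1
        onsets = np.arange(0, n, dur)
        phi = 2 * np.pi * np.arange(n) / dur
        X = np.column_stack([np.sin(phi), np.cos(phi)] * 3)
        phase, idx = step_phase_annotation(n, onsets)
        traj = StateTrajectory(X, "diff", 0.01, phase=phase, step_index=idx)
        with pytest.raises(BoutRejected):
            reaction_curve(traj, StepSeries(onsets, 100.0), 0.0)

    def test_too_few_cycles_rejected(self, rng):
        traj, steps = _toy_trajectory(rng, n_cycles=5)
        with pytest.raises(BoutRejected):
            reaction_curve(traj, steps, 0.0)

    def test_initial_distance_matches_exhaustive_oracle(self, rng):
        traj, steps = _toy_trajectory(rng, n_cycles=20)
        prm = StabilityParams(min_neighbors=2, theiler_strides=1)
        phase = 0.2
        curve = reaction_curve(traj, steps, phase, prm)

        # O(n^2) oracle: same definition, independent implementation
        X = traj.points
        onsets = steps.onsets
        durs = np.diff(onsets)
        pts = onsets[:-1] + np.round(phase * durs).astype(int)
        centroid = X.mean(axis=0)
        radius = prm.radius_factor * np.sqrt(
            np.mean(np.sum((X - centroid) ** 2, axis=1))
        )
        ctimes = durs / steps.sample_rate
        lo, hi = np.percentile(ctimes, prm.stride_time_percentiles)
        per_ref = []
        for k in range(len(pts)):
            if not (lo <= ctimes[k] <= hi):
                continue
            L = onsets[k + 1] - pts[k]
            dists = []
            for m in range(len(pts)):
                if abs(m - k) <= prm.theiler_strides or pts[m] + L > len(X):
                    continue
                d = np.linalg.norm(X[pts[k]] - X[pts[m]])
                if 1e-10 < d <= radius:
                    dists.append(d)
            if len(dists) >= prm.min_neighbors:
                per_ref.append(np.mean(sorted(dists)[: prm.max_neighbors]))
        oracle = np.mean(per_ref)
        assert curve.initial_distance() == pytest.approx(oracle, rel=1e-9)

    def test_exclusion_fraction_below_ten_percent_on_defaults(self, analyzed_bout):
        out = compute_bout_lambdas(
            analyzed_bout["traj_diff"], analyzed_bout["traj_lag"], analyzed_bout["steps"]
        )
        assert out["excluded_fraction_diff"] < 0.10
        assert out["excluded_fraction_lag"] < 0.10

    def test_scale_invariance(self, rng):
        traj, steps = _toy_trajectory(rng, n_cycles=20)
        scaled = StateTrajectory(
            traj.points * 17.3, "diff", 0.01, phase=traj.phase, step_index=traj.step_index
        )
        prm = StabilityParams(min_neighbors=2)
        c1 = reaction_curve(traj, steps, 0.2, prm)
        c2 = reaction_curve(scaled, steps, 0.2, prm)
        assert lambda_eq1(c1) == pytest.approx(lambda_eq1(c2), rel=1e-9)
        assert lambda_eq2(c1) == pytest.approx(lambda_eq2(c2), rel=1e-9)


class TestRecovery:
    def test_contraction_ordering_recovered(self):
        """More persistent perturbations at a phase -> larger estimated λ."""
        lams = {}
        for c0 in (-1.2, -0.05):
            vals = []
            for seed in (3, 4):
                cfg = GaitSimConfig(
                    seed=seed,
                    bouts_per_subject=1,
                    bout_count_jitter=0,
                    bout_duration_jitter=0.0,
                    contraction_subject_sd=0.0,
                    subject_freq_sd=0.0,
                    subject_amp_sd=0.0,
                    subject_cv_sd=0.0,
                    phase_contraction={"faller": (c0, -0.3, -0.3, c0, -0.3)},
                    ar_persistence=tuple(np.exp([-0.4] * 5)),
                )
                rec, truth = simulate_subject(cfg, "S", "faller", 0)
                from conftest import preprocess_bout

                b = truth.bouts[0]
                acc = rec.acc[b.start_index : b.end_index]
                det, vel, steps, td, tl = preprocess_bout(acc, 100.0)
                out = compute_bout_lambdas(td, tl, steps, phases=(0.0, 0.6))
                vals.append(np.nanmean([out["lambda_diff_p0_eq1"], out["lambda_diff_p60_eq1"]]))
            lams[c0] = np.mean(vals)
        assert lams[-0.05] > lams[-1.2]


class TestWolf:
    def test_periodic_signal_near_zero(self):
        t = np.arange(6000) / 100.0
        x = np.sin(2 * np.pi * t) + 0.3 * np.sin(4 * np.pi * t + 0.5)
        assert abs(wolf_lambda(x, 100.0)) < 0.05

    def test_lorenz_vs_benettin(self, lorenz_data):
        x, lam_ben = lorenz_data
        lam_wolf = wolf_lambda(x, 100.0)
        assert abs(lam_wolf - lam_ben) / lam_ben < 0.25

    def test_noise_exceeds_periodic(self, rng):
        t = np.arange(6000) / 100.0
        periodic = np.sin(2 * np.pi * t)
        noise = rng.standard_normal(6000)
        assert wolf_lambda(noise, 100.0) > wolf_lambda(periodic, 100.0)

    def test_too_short_raises(self, rng):
        with pytest.raises(DataError):
            wolf_lambda(rng.standard_normal(50), 100.0)
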