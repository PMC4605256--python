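import numpy as np
import pytest

from gaitdyn.bout_detection import detect_walking_bouts
from gaitdyn.embedding import embed_delayed, embed_differential
from gaitdyn.preprocess import (
    detect_steps,
    estimate_stride_period,
    integrate_to_velocity,
    wavelet_detrend,
)
from gaitdyn.synthetic_data import GaitSimConfig, simulate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def preprocess_bout(acc, fs):
    """Standard per-bout chain: detrend -> velocity -> steps -> embeddings."""
    sp = estimate_stride_period(acc[:, 2], fs)
    det = np.column_stack([wavelet_detrend(acc[:, j], fs, sp) for j in range(3)])
    vel = integrate_to_velocity(det, fs, sp)
    steps = detect_steps(vel)
    traj_diff = embed_differential(det, vel.vel, steps, dt=1.0 / fs)
    traj_lag = embed_delayed(vel.vel, 3, steps, dt=1.0 / fs)
    return det, vel, steps, traj_diff, traj_lag


@pytest.fixture(scope="session")
def default_subject():
    """One simulated faller recording plus its ground truth (2 bouts)."""
    cfg = GaitSimConfig(seed=7, bouts_per_subject=2, bout_count_jitter=0)
    rec, truth = simulate_subject(cfg, "S01", "faller", 0)
    return rec, truth, cfg


@pytest.fixture(scope="session")
def analyzed_bout(default_subject):
    """First detected bout of the default subject, fully preprocessed."""
    rec, truth, cfg = default_subject
    bout = detect_walking_bouts(rec)[0]
    acc = rec.acc[bout.start_index : bout.end_index]
    det, vel, steps, traj_diff, traj_lag = preprocess_bout(acc, rec.sample_rate)
    return {
        "rec": rec,
        "truth": truth,
        "bout": bout,
        "acc": acc,
        "det": det,
        "vel": vel,
        "steps": steps,
        "traj_diff": traj_diff,
        "traj_lag": traj_lag,
    }


# ---------------------------------------------------------------------------
# shared oracles


def lorenz_x_series(n=20000, dt=0.01, transient=2000):
    """Lorenz x-coordinate trajectory plus a Benettin tangent-vector oracle
    for the largest Lyapunov exponent, integrated with fixed-step RK4."""
    sigma, rho, beta = 10.0, 28.0, 8.0 / 3.0

    def f(s):
        x, y, z = s
        return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])

    def jac(s):
        x, y, z = s
        return np.array([[-sigma, sigma, 0.0], [rho - z, -1.0, -x], [y, x, -beta]])

    def rk4(s, h, func):
        k1 = func(s)
        k2 = func(s + h / 2 * k1)
        k3 = func(s + h / 2 * k2)
        k4 = func(s + h * k3)
        return s + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)

    s = np.array([1.0, 1.0, 20.0])
    for _ in range(transient):
        s = rk4(s, dt, f)
    v = np.array([1.0, 0.0, 0.0])
    log_sum = 0.0
    x_series = np.empty(n)
    for i in range(n):
        x_series[i] = s[0]
        s_half = rk4(s, dt / 2, f)
        s_full = rk4(s, dt, f)
        k1 = jac(s) @ v
        k2 = jac(s_half) @ (v + dt / 2 * k1)
        k3 = jac(s_half) @ (v + dt / 2 * k2)
        k4 = jac(s_full) @ (v + dt * k3)
        v = v + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        s = s_full
        nv = np.linalg.norm(v)
        log_sum += np.log(nv)
        v /= nv
    lam_benettin = log_sum / (n * dt)
    return x_series, lam_benettin


@pytest.fixture(scope="session")
def lorenz_data():
    return lorenz_x_series()
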