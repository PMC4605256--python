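"""End-to-end orchestration: recordings -> bouts -> features -> PLS-DA.

``run_pipeline`` consumes either a synthetic cohort (generated in-process
from a :class:`~gaitdyn.synthetic_data.GaitSimConfig`) or a manifest of
columnar recording files, and produces the full results bundle: a subject
feature table, per-subject exponent table, discriminant metrics for the
three predictor matrices, target-projection loadings, group comparison and
test-retest ICCs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import gait_features as gf
from .bout_detection import BoutDetectionParams, detect_walking_bouts, read_recording
from .core import AXES, BoutRejected, DataError, TriaxialRecording
from .embedding import embed_delayed, embed_differential
from .preprocess import (
    StepDetectionParams,
    detect_steps,
    estimate_stride_period,
    integrate_to_velocity,
    wavelet_detrend,
)
from .stability import (
    StabilityParams,
    WolfParams,
    compute_bout_lambdas,
    subject_lambda,
    wolf_lambda,
)
from .stats import cross_validate, fit_pls_nipals, group_compare, icc_absolute, target_projection
from .synthetic_data import GaitSimConfig, simulate_cohort

log = logging.getLogger("gaitdyn")

#: bout-level feature columns aggregated to subject level by the median
_BOUT_LEVEL = [f"{ax}_{feat}" for feat in gf.PER_AXIS_FEATURES for ax in AXES]


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # "synthetic" | "real-data"
    manifest: Optional[str] = None
    outdir: Optional[str] = None
    seed: int = 0
    sim: GaitSimConfig = None
    bout_params: BoutDetectionParams = field(default_factory=BoutDetectionParams)
    step_params: StepDetectionParams = field(default_factory=StepDetectionParams)
    stability_params: StabilityParams = field(default_factory=StabilityParams)
    # coarser evolution than the WolfParams defaults: λ_wolf is one bout
    # feature among many here and the finer settings cost ~4x the time
    wolf_params: WolfParams = field(
        default_factory=lambda: WolfParams(evolve_s=0.15, max_scale_fraction=0.05)
    )
    wolf_max_samples: int = 5000  # truncate long bouts for λ_wolf
    delayed_lag: int = 3
    n_components: int = 4
    compute_wolf: bool = True
    max_bouts_per_subject: Optional[int] = None

    def __post_init__(self):
        if self.mode not in ("synthetic", "real-data"):
            raise DataError(f"unknown run mode {self.mode!r}")
        if self.mode == "synthetic" and self.sim is None:
            self.sim = GaitSimConfig(seed=self.seed)

    def hash(self) -> str:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if hasattr(o, "__dataclass_fields__"):
                return asdict(o)
            return str(o)

        payload = asdict(self)
        payload.pop("outdir", None)  # scientific parameters only
        blob = json.dumps(payload, default=enc, sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def analyze_subject(rec: TriaxialRecording, cfg: PipelineConfig) -> Dict:
    """All bout-level and subject-level quantities for one recording.

    Returns a dict with the 46-entry feature row (missing -> NaN), the
    per-bout exponent table, and per-stage counts for the run log.
    """
    bouts = detect_walking_bouts(rec, cfg.bout_params)
    if cfg.max_bouts_per_subject is not None:
        bouts = bouts[: cfg.max_bouts_per_subject]
    fs = rec.sample_rate
    bout_rows: List[Dict] = []
    n_rejected = 0
    for bi, bout in enumerate(bouts):
        acc = rec.acc[bout.start_index : bout.end_index]
        try:
            stride_est = estimate_stride_period(acc[:, 2], fs)
            det = np.column_stack(
                [wavelet_detrend(acc[:, j], fs, stride_est) for j in range(3)]
            )
            vel = integrate_to_velocity(det, fs, stride_est)
            steps = detect_steps(vel, cfg.step_params)
        except (BoutRejected, DataError) as exc:
            log.info("subject %s bout %d rejected: %s", rec.subject_id, bi, exc)
            n_rejected += 1
            continue
        row: Dict = {"bout_idx": bi, "duration": bout.duration,
                     "n_steps": steps.n_steps,
                     "mean_step_time": steps.mean_step_time,
                     "mean_stride_time": steps.mean_stride_time}
        row.update(gf.bout_axis_features(det, fs, steps))
        traj_diff = embed_differential(det, vel.vel, steps, dt=1.0 / fs)
        traj_lag = embed_delayed(vel.vel, cfg.delayed_lag, steps, dt=1.0 / fs)
        row.update(
            compute_bout_lambdas(traj_diff, traj_lag, steps, cfg.stability_params)
        )
        if cfg.compute_wolf:
            wolf_seg = det[: cfg.wolf_max_samples]
            for j, ax in enumerate(AXES):
                try:
                    row[f"{ax}_lambda_wolf"] = wolf_lambda(
                        wolf_seg[:, j], fs, cfg.wolf_params
                    )
                except DataError:
                    row[f"{ax}_lambda_wolf"] = np.nan
        else:
            for ax in AXES:
                row[f"{ax}_lambda_wolf"] = np.nan
        bout_rows.append(row)

    bout_df = pd.DataFrame(bout_rows)
    feature_row: Dict[str, float] = {name: np.nan for name in gf.feature_names()}
    if len(bout_df):
        lambda_cols = [c for c in bout_df.columns if c.startswith("lambda_")]
        wolf_cols = [f"{ax}_lambda_wolf" for ax in AXES]
        for col in _BOUT_LEVEL + lambda_cols + wolf_cols:
            feature_row[col] = subject_lambda(bout_df[col])
        feature_row.update(
            gf.timing_features(
                bout_df["duration"],
                bout_df["n_steps"],
                bout_df["mean_step_time"],
                bout_df["mean_stride_time"],
                rec.duration,
            )
        )
    return {
        "features": feature_row,
        "bout_table": bout_df,
        "n_bouts_detected": len(bouts),
        "n_bouts_rejected": n_rejected,
    }


def _split_thirds_icc(bout_tables: Dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Test-retest ICC of the phase exponents: first vs last 1/3 of bouts."""
    rows = []
    for feat in gf.PHASE_LAMBDA_FEATURES:
        test, retest = [], []
        for sid, bt in bout_tables.items():
            if feat not in bt.columns or len(bt) < 3:
                continue
            third = len(bt) // 3
            test.append(subject_lambda(bt[feat].iloc[:third]))
            retest.append(subject_lambda(bt[feat].iloc[-third:]))
        try:
            res = icc_absolute(np.array(test), np.array(retest))
            rows.append({"feature": feat, "icc": res.icc,
                         "ci_low": res.ci_low, "ci_high": res.ci_high, "n": res.n})
        except DataError as exc:
            log.info("ICC for %s unavailable: %s", feat, exc)
            rows.append({"feature": feat, "icc": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "n": 0})
    return pd.DataFrame(rows).set_index("feature")


def run_pipeline(cfg: PipelineConfig) -> Dict:
    """Run the full analysis; returns (and optionally writes) the bundle."""
    if cfg.mode == "synthetic":
        recordings, manifest, _truths = simulate_cohort(cfg.sim)
    else:
        if cfg.manifest is None:
            raise DataError("real-data mode needs a manifest path")
        manifest = pd.read_csv(cfg.manifest)
        base = Path(cfg.manifest).parent
        recordings = []
        for _, r in manifest.iterrows():
            rec = read_recording(base / r["file"])
            rec.subject_id = str(r["subject_id"])
            rec.group = str(r["group"])
            recordings.append(rec)
    if len(recordings) == 0:
        raise DataError("empty cohort")

    feature_rows = {}
    bout_tables = {}
    counts = {}
    for rec in recordings:
        res = analyze_subject(rec, cfg)
        feature_rows[rec.subject_id] = res["features"]
        bout_tables[rec.subject_id] = res["bout_table"]
        counts[rec.subject_id] = {
            "n_bouts_detected": res["n_bouts_detected"],
            "n_bouts_rejected": res["n_bouts_rejected"],
        }
        log.info(
            "subject %s: %d bouts, %d rejected",
            rec.subject_id,
            res["n_bouts_detected"],
            res["n_bouts_rejected"],
        )

    features = pd.DataFrame.from_dict(feature_rows, orient="index")
    features.index.name = "subject_id"
    groups = manifest.set_index("subject_id")["group"]
    y = (groups.loc[features.index] == "faller").astype(int).to_numpy()

    x1, x2, x3 = gf.assemble_matrices(features)
    kept = x1.index
    yk = (groups.loc[kept] == "faller").astype(int).to_numpy()

    metrics = {}
    rocs = {}
    for name, X in (("X1", x1), ("X2", x2), ("X3", x3)):
        m = cross_validate(X.to_numpy(), yk, n_components=cfg.n_components)
        metrics[name] = {
            "sensitivity": round(float(m.sensitivity), 6),
            "specificity": round(float(m.specificity), 6),
            "auc": round(float(m.auc), 6),
            "error": round(float(m.error), 6),
        }
        rocs[name] = m.roc

    model = fit_pls_nipals(x1.to_numpy(), yk, n_components=cfg.n_components, scale=False)
    _, tp = target_projection(model, x1.to_numpy(), yk)
    tp_table = (
        pd.DataFrame({"feature": x1.columns, "tp_loading": tp})
        .assign(abs_loading=lambda d: d["tp_loading"].abs())
        .sort_values("abs_loading", ascending=False)
        .set_index("feature")
    )

    comparison = group_compare(features.loc[kept], groups.loc[kept].to_numpy())
    icc_table = _split_thirds_icc(bout_tables)

    bundle = {
        "config_hash": cfg.hash(),
        "metrics": metrics,
        "tp_loadings": tp_table,
        "group_comparison": comparison,
        "icc": icc_table,
        "features": features,
        "labels": pd.Series(yk, index=kept, name="faller"),
        "bout_tables": bout_tables,
        "rocs": rocs,
        "counts": counts,
    }
    if cfg.outdir is not None:
        write_bundle(bundle, cfg.outdir)
    return bundle


def write_bundle(bundle: Dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = bundle["config_hash"]

    def _csv(df: pd.DataFrame, name: str):
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(f"# config_hash: {h}\n")
            df.to_csv(fh, float_format="%.10g")

    _csv(bundle["features"], "features.csv")
    _csv(bundle["tp_loadings"], "tp_loadings.csv")
    _csv(bundle["group_comparison"], "group_comparison.csv")
    _csv(bundle["icc"], "icc.csv")
    _csv(_lambda_long_table(bundle), "lambda.csv")
    for name, roc in bundle["rocs"].items():
        _csv(pd.DataFrame(roc, columns=["fpr", "tpr"]), f"roc_{name}.csv")
    payload = {
        "config_hash": h,
        "metrics": bundle["metrics"],
        "counts": bundle["counts"],
    }
    (outdir / "metrics.json").write_text(json.dumps(payload, sort_keys=True, indent=1))


def _lambda_long_table(bundle: Dict) -> pd.DataFrame:
    """Per-subject exponent table: subject_id, phase, equation, embedding,
    lambda, n_bouts."""
    rows = []
    for sid, feats in bundle["features"].iterrows():
        bt = bundle["bout_tables"].get(sid)
        for col in feats.index:
            if not col.startswith("lambda_"):
                continue
            _, emb, ph, eq = col.split("_")
            n_bouts = int(bt[col].notna().sum()) if bt is not None and col in bt else 0
            rows.append(
                {
                    "subject_id": sid,
                    "phase": int(ph[1:]),
                    "equation": int(eq[2:]),
                    "embedding": emb,
                    "lambda": feats[col],
                    "n_bouts": n_bouts,
                }
            )
    return pd.DataFrame(rows).set_index("subject_id")


def make_report(bundle: Dict, plot_dir=None) -> str:
    """Human-readable summary mirroring the metrics / ranking / ICC tables."""
    lines = [f"gaitdyn results (config {bundle['config_hash']})", ""]
    lines.append("Classification performance (LOO cross-validated):")
    lines.append(f"{'':14s}" + "".join(f"{m:>10s}" for m in bundle["metrics"]))
    for key in ("sensitivity", "specificity", "auc", "error"):
        row = "".join(f"{bundle['metrics'][m][key]:10.3f}" for m in bundle["metrics"])
        lines.append(f"{key:14s}{row}")
    lines.append("")
    lines.append("Top 10 features by |TP loading|:")
    top = bundle["tp_loadings"].head(10)
    for feat, r in top.iterrows():
        lines.append(f"  {feat:28s} {r['tp_loading']:+.3f}")
    lines.append("")
    if "icc" in bundle and len(bundle["icc"]):
        if bundle["icc"]["icc"].isna().all():
            lines.append("ICC section unavailable (insufficient bouts).")
        else:
            lines.append("Test-retest ICC (first vs last 1/3 of bouts):")
            for feat, r in bundle["icc"].iterrows():
                lines.append(
                    f"  {feat:28s} {r['icc']:.3f} [{r['ci_low']:.3f}, {r['ci_high']:.3f}]"
                )
    else:
        lines.append("ICC section missing.")
    if plot_dir is not None:
        _plots(bundle, plot_dir)
    return "\n".join(lines)


def _plots(bundle: Dict, plot_dir) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir = Path(plot_dir)
    plot_dir.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots()
    for name, roc in bundle["rocs"].items():
        ax.plot(roc[:, 0], roc[:, 1], label=f"{name} (AUC {bundle['metrics'][name]['auc']:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    fig.savefig(plot_dir / "roc.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 10))
    tpl = bundle["tp_loadings"].sort_values("abs_loading")
    ax.barh(np.arange(len(tpl)), tpl["tp_loading"])
    ax.set_yticks(np.arange(len(tpl)))
    ax.set_yticklabels(tpl.index, fontsize=5)
    ax.set_xlabel("TP loading")
    fig.tight_layout()
    fig.savefig(plot_dir / "tp_loadings.png", dpi=120)
    plt.close(fig)
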