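"""Discriminant analysis and reliability statistics.

PLS-DA is implemented as classical NIPALS PLS1 against a 0/1 class code,
extended with a target projection that rotates the fitted model onto its
single predictive direction: one score per subject (``V``) and one loading
in [-1, 1] per feature ranking its discriminant contribution.

Also provided: leave-one-out cross-validated classification metrics with
fold-internal z-scoring, rank-based ROC/AUC, two-way absolute-agreement
ICC for test-retest splits, and per-feature Mann-Whitney group comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core import ConfigurationError, DataError


# ---------------------------------------------------------------------------
# NIPALS PLS1 + target projection


@dataclass
class PLSModel:
    weights: np.ndarray  # W, (n_features, A)
    x_loadings: np.ndarray  # P, (n_features, A)
    y_weights: np.ndarray  # c, (A,)
    scores: np.ndarray  # T, (n_subjects, A)
    coef: np.ndarray  # B, (n_features,): yhat = Xz @ B + y_mean
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    n_components: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_mean) / self.x_std

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.transform(X) @ self.coef + self.y_mean


def fit_pls_nipals(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int = 4,
    scale: bool = True,
    allow_constant: bool = False,
) -> PLSModel:
    """Classical NIPALS PLS1: w = X'y (unit norm), t = Xw, deflate, repeat.

    A zero-variance column is an error unless ``allow_constant`` (a column
    can legitimately become constant inside a cross-validation fold); an
    allowed constant column is centred to zeros and receives zero weight.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != len(X):
        raise DataError("X must be (n, p) with matching y")
    if np.isnan(X).any() or np.isnan(y).any():
        raise DataError("missing entries in X or y")
    n, p = X.shape
    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0, ddof=1) if scale else np.ones(p)
    if np.any(x_std == 0):
        if not allow_constant:
            raise DataError("zero-variance feature column")
        x_std = np.where(x_std == 0, 1.0, x_std)
    Xz = (X - x_mean) / x_std
    y_mean = float(y.mean())
    yc = y - y_mean

    rank = np.linalg.matrix_rank(Xz)
    A = n_components
    if A > rank:
        warnings.warn(f"n_components={n_components} > rank {rank}; truncating")
        A = rank

    Xd, yd = Xz.copy(), yc.copy()
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    T = np.zeros((n, A))
    c = np.zeros(A)
    for a in range(A):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            A = a
            W, P, T, c = W[:, :A], P[:, :A], T[:, :A], c[:A]
            break
        w /= norm
        t = Xd @ w
        tt = t @ t
        ca = (t @ yd) / tt
        pa = Xd.T @ t / tt
        Xd = Xd - np.outer(t, pa)
        yd = yd - ca * t
        W[:, a], P[:, a], T[:, a], c[a] = w, pa, t, ca
    if A == 0:
        raise DataError("X carries no covariance with y")
    # B such that yhat = Xz @ B + y_mean
    B = W @ np.linalg.solve(P.T @ W, c)
    return PLSModel(
        weights=W,
        x_loadings=P,
        y_weights=c,
        scores=T,
        coef=B,
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        n_components=A,
    )


def target_projection(model: PLSModel, X: np.ndarray, y: Optional[np.ndarray] = None):
    """Target-projection scores V and per-feature TP loadings.

    V is the projection of (z-scored) X onto the normalised regression
    vector; loadings are the correlations between each feature column and
    V, so they lie in [-1, 1].  The sign convention puts the positive end
    of V towards the class coded 1 when ``y`` is given.
    """
    bnorm = np.linalg.norm(model.coef)
    if bnorm < 1e-12:
        raise DataError("degenerate PLS model: B ~ 0")
    Xz = model.transform(X)
    V = Xz @ model.coef / bnorm
    if y is not None and np.cov(V, np.asarray(y, dtype=float))[0, 1] < 0:
        V = -V
    Vc = V - V.mean()
    vv = Vc @ Vc
    col_ss = np.sum((Xz - Xz.mean(axis=0)) ** 2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        loadings = (Xz - Xz.mean(axis=0)).T @ Vc / np.sqrt(col_ss * vv)
    loadings = np.nan_to_num(loadings)  # zero-variance columns load 0
    return V, loadings


# ---------------------------------------------------------------------------
# ROC / AUC


def roc_auc(scores: np.ndarray, labels: np.ndarray):
    """ROC points (fpr, tpr) and AUC via the rank (Mann-Whitney) identity."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise DataError("ROC requires both classes")
    ranks = sstats.rankdata(scores)
    auc = (ranks[labels == 1].sum() - len(pos) * (len(pos) + 1) / 2) / (
        len(pos) * len(neg)
    )
    thresholds = np.concatenate([[np.inf], np.sort(np.unique(scores))[::-1]])
    tpr = [(pos >= th).mean() for th in thresholds]
    fpr = [(neg >= th).mean() for th in thresholds]
    roc = np.column_stack([fpr, tpr])
    return roc, float(auc)


# ---------------------------------------------------------------------------
# cross-validated PLS-DA


@dataclass
class ClassificationMetrics:
    sensitivity: float
    specificity: float
    auc: float
    error: float
    roc: np.ndarray
    scores: np.ndarray  # cross-validated predicted scores, one per subject


def cross_validate(
    X: np.ndarray, y: np.ndarray, n_components: int = 4, threshold: float = 0.5
) -> ClassificationMetrics:
    """Leave-one-out PLS-DA with fold-internal z-scoring.

    Class coding: 0 = nonfaller (negative), 1 = faller (positive); a
    held-out subject is called positive when its predicted score exceeds
    ``threshold`` (midpoint of the class codes).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n = len(y)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise DataError("need >= 2 subjects per class")
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            warnings.warn("single-class training fold skipped")
            preds[i] = np.nan
            continue
        model = fit_pls_nipals(
            X[mask], y[mask], n_components=n_components, allow_constant=True
        )
        preds[i] = model.predict(X[i : i + 1])[0]
    ok = np.isfinite(preds)
    yhat = (preds[ok] > threshold).astype(int)
    yk = y[ok]
    tp = int(np.sum((yhat == 1) & (yk == 1)))
    tn = int(np.sum((yhat == 0) & (yk == 0)))
    fp = int(np.sum((yhat == 1) & (yk == 0)))
    fn = int(np.sum((yhat == 0) & (yk == 1)))
    roc, auc = roc_auc(preds[ok], yk)
    return ClassificationMetrics(
        sensitivity=tp / (tp + fn) if tp + fn else np.nan,
        specificity=tn / (tn + fp) if tn + fp else np.nan,
        auc=auc,
        error=(fp + fn) / len(yk),
        roc=roc,
        scores=preds,
    )


# ---------------------------------------------------------------------------
# ICC (two-way, absolute agreement, single measures)


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n: int
    split: str = "first vs last 1/3 of bouts"


def icc_absolute(
    test: np.ndarray, retest: np.ndarray, alpha: float = 0.05
) -> ICCResult:
    """ICC(A,1): two-way model, absolute agreement, single measures."""
    t1 = np.asarray(test, dtype=float)
    t2 = np.asarray(retest, dtype=float)
    ok = np.isfinite(t1) & np.isfinite(t2)
    t1, t2 = t1[ok], t2[ok]
    n = len(t1)
    if n < 5:
        raise DataError("ICC needs >= 5 paired observations")
    k = 2
    data = np.column_stack([t1, t2])
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or msr <= 0:
        raise DataError("degenerate variance structure for ICC")
    icc = (msr - mse) / denom

    # McGraw & Wong (1996) confidence bounds for ICC(A,1)
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and mse > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = sstats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = sstats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    else:
        lo = hi = 1.0
    return ICCResult(icc=float(icc), ci_low=float(min(lo, icc)),
                     ci_high=float(max(hi, icc)), n=n)


# ---------------------------------------------------------------------------
# group comparison


def group_compare(features: pd.DataFrame, labels: Sequence) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per feature + group means/SDs.

    No multiple-testing correction is applied; p-values are reported raw.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ConfigurationError("group_compare needs exactly 2 groups")
    g0 = features.loc[labels == groups[0]]
    g1 = features.loc[labels == groups[1]]
    rows = []
    for col in features.columns:
        a = g0[col].dropna().to_numpy()
        b = g1[col].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2 or (np.ptp(np.concatenate([a, b])) == 0):
            p = np.nan
            u = np.nan
        else:
            u, p = sstats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "feature": col,
                "U": u,
                "p_value": p,
                f"mean_{groups[0]}": a.mean() if len(a) else np.nan,
                f"sd_{groups[0]}": a.std(ddof=1) if len(a) > 1 else np.nan,
                f"mean_{groups[1]}": b.mean() if len(b) else np.nan,
                f"sd_{groups[1]}": b.std(ddof=1) if len(b) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("feature")
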