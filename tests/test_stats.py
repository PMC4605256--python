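import numpy as np
import pytest
from scipy import stats as sstats

from gaitdyn.core import ConfigurationError, DataError
from gaitdyn.stats import (
    cross_validate,
    fit_pls_nipals,
    group_compare,
    icc_absolute,
    roc_auc,
    target_projection,
)

import pandas as pd


def svd_pls1_oracle(X, y, n_components):
    """Independent PLS1: per component the weight vector is the leading
    eigenvector of X' y y' X (computed by eigendecomposition), then deflate."""
    Xz = (X - X.mean(0)) / X.std(0, ddof=1)
    yc = y - y.mean()
    Xd, yd = Xz.copy(), yc.astype(float).copy()
    W, T = [], []
    for _ in range(n_components):
        M = np.outer(Xd.T @ yd, Xd.T @ yd)
        vals, vecs = np.linalg.eigh(M)
        w = vecs[:, np.argmax(vals)]
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        c = t @ yd / (t @ t)
        Xd = Xd - np.outer(t, p)
        yd = yd - c * t
        W.append(w)
        T.append(t)
    return np.column_stack(W), np.column_stack(T)


class TestNIPALS:
    def test_matches_svd_oracle_up_to_sign(self, rng):
        X = rng.standard_normal((10, 5))
        y = rng.integers(0, 2, 10).astype(float)
        model = fit_pls_nipals(X, y, n_components=3)
        W_o, T_o = svd_pls1_oracle(X, y, 3)
        for a in range(3):
            s = np.sign(model.weights[:, a] @ W_o[:, a])
            np.testing.assert_allclose(model.weights[:, a], s * W_o[:, a], atol=1e-8)
            np.testing.assert_allclose(model.scores[:, a], s * T_o[:, a], atol=1e-8)

    def test_perfect_single_predictor(self, rng):
        y = np.array([0, 1, 0, 1, 1, 0, 1, 0], dtype=float)
        X = y[:, None] * 2.0 + 3.0
        model = fit_pls_nipals(X, y, n_components=1)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-10)

    def test_irrelevant_column_zero_weight(self, rng):
        y = np.tile([0.0, 1.0], 10)
        signal = y + 0.01 * rng.standard_normal(20)
        # column orthogonal to y and to the signal column
        junk = np.tile([1.0, 1.0, -1.0, -1.0], 5)
        X = np.column_stack([signal, junk])
        model = fit_pls_nipals(X, y, n_components=1)
        assert abs(model.weights[1, 0]) < 0.05

    def test_score_orthogonality(self, rng):
        X = rng.standard_normal((30, 12))
        y = rng.integers(0, 2, 30).astype(float)
        model = fit_pls_nipals(X, y, n_components=4)
        G = model.scores.T @ model.scores
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8

    def test_coef_equals_componentwise_prediction(self, rng):
        X = rng.standard_normal((25, 8))
        y = rng.integers(0, 2, 25).astype(float)
        model = fit_pls_nipals(X, y, n_components=4)
        via_components = model.scores @ model.y_weights + model.y_mean
        np.testing.assert_allclose(model.predict(X), via_components, atol=1e-8)

    def test_rank_truncation_warns(self, rng):
        X = rng.standard_normal((5, 10))
        y = rng.integers(0, 2, 5).astype(float)
        with pytest.warns(UserWarning):
            model = fit_pls_nipals(X, y, n_components=8)
        assert model.n_components < 8

    def test_zero_variance_column_raises(self, rng):
        X = rng.standard_normal((10, 3))
        X[:, 1] = 2.0
        with pytest.raises(DataError):
            fit_pls_nipals(X, np.tile([0.0, 1.0], 5), n_components=2)


class TestTargetProjection:
    def test_y_like_column_maximal_loading(self, rng):
        y = np.tile([0.0, 1.0], 15)
        X = np.column_stack([y, rng.standard_normal((30, 4))])
        model = fit_pls_nipals(X, y, n_components=3)
        V, tp = target_projection(model, X, y)
        assert abs(tp[0]) > 0.99

    def test_one_component_tp_proportional_to_weights(self, rng):
        # with uncorrelated columns the single-component TP loadings align
        # with the weight vector after normalisation
        X = rng.standard_normal((5000, 6))
        y = rng.integers(0, 2, 5000).astype(float)
        model = fit_pls_nipals(X, y, n_components=1)
        _, tp = target_projection(model, X, y)
        w = model.weights[:, 0]
        np.testing.assert_allclose(
            tp / np.linalg.norm(tp), w / np.linalg.norm(w), atol=0.05
        )

    def test_noise_feature_small_loading(self, rng):
        n = 400
        y = rng.integers(0, 2, n).astype(float)
        signal = y + 0.3 * rng.standard_normal(n)
        noise = rng.standard_normal(n)
        X = np.column_stack([signal, noise])
        model = fit_pls_nipals(X, y, n_components=2)
        _, tp = target_projection(model, X, y)
        assert abs(tp[1]) < 0.2

    def test_loadings_in_unit_interval(self, rng):
        X = rng.standard_normal((50, 10))
        y = rng.integers(0, 2, 50).astype(float)
        model = fit_pls_nipals(X, y, n_components=4)
        _, tp = target_projection(model, X, y)
        assert np.all(np.abs(tp) <= 1.0 + 1e-12)

    def test_ranking_invariant_to_column_scaling(self, rng):
        X = rng.standard_normal((50, 10))
        y = rng.integers(0, 2, 50).astype(float)
        m1 = fit_pls_nipals(X, y, n_components=4)
        _, tp1 = target_projection(m1, X, y)
        X2 = X * np.linspace(0.1, 30, 10)[None, :]
        m2 = fit_pls_nipals(X2, y, n_components=4)
        _, tp2 = target_projection(m2, X2, y)
        assert list(np.argsort(np.abs(tp1))) == list(np.argsort(np.abs(tp2)))


class TestCrossValidate:
    def test_perfectly_separable(self, rng):
        y = np.repeat([0, 1], 15)
        X = np.column_stack([y + 0.01 * rng.standard_normal(30),
                             rng.standard_normal(30)])
        m = cross_validate(X, y, n_components=2)
        assert m.sensitivity == 1.0
        assert m.specificity == 1.0
        assert m.auc == 1.0
        assert m.error == 0.0

    def test_permuted_labels_chance_level(self, rng):
        n = 60
        X = rng.standard_normal((n, 8))
        y = rng.permutation(np.repeat([0, 1], n // 2))
        m = cross_validate(X, y, n_components=4)
        assert 0.25 <= m.auc <= 0.75

    def test_error_identity(self, rng):
        n = 40
        X = rng.standard_normal((n, 5))
        X[:, 0] += np.repeat([0.0, 1.0], n // 2)
        y = np.repeat([0, 1], n // 2)
        m = cross_validate(X, y, n_components=2)
        preds = (m.scores > 0.5).astype(int)
        tp = np.sum((preds == 1) & (y == 1))
        tn = np.sum((preds == 0) & (y == 0))
        assert m.error == pytest.approx(1.0 - (tp + tn) / n, abs=1e-12)

    def test_needs_two_per_class(self, rng):
        X = rng.standard_normal((4, 3))
        with pytest.raises(DataError):
            cross_validate(X, np.array([0, 0, 0, 1]))


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert auc == 1.0

    def test_all_ties(self):
        _, auc = roc_auc(np.ones(10), np.tile([0, 1], 5))
        assert auc == 0.5

    def test_all_pairs_oracle(self, rng):
        scores = rng.standard_normal(20)
        scores[3] = scores[11]  # inject a tie
        labels = rng.integers(0, 2, 20)
        labels[:2] = 1
        labels[-2:] = 0
        _, auc = roc_auc(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_antisymmetry(self, rng):
        scores = rng.standard_normal(30)
        labels = rng.integers(0, 2, 30)
        labels[0], labels[1] = 0, 1
        _, a1 = roc_auc(scores, labels)
        _, a2 = roc_auc(-scores, labels)
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_roc_monotone(self, rng):
        scores = rng.standard_normal(50)
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1
        roc, _ = roc_auc(scores, labels)
        assert np.all(np.diff(roc[:, 0]) >= 0)
        assert np.all(np.diff(roc[:, 1]) >= 0)

    def test_single_class_raises(self):
        with pytest.raises(DataError):
            roc_auc(np.arange(5.0), np.ones(5))


def anova_icc_oracle(t1, t2):
    """Explicit two-way mean squares for ICC(A,1), k = 2."""
    data = np.column_stack([t1, t2]).astype(float)
    n, k = data.shape
    grand = data.mean()
    ms_rows = k * np.sum((data.mean(axis=1) - grand) ** 2) / (n - 1)
    ms_cols = n * np.sum((data.mean(axis=0) - grand) ** 2) / (k - 1)
    sse = np.sum((data - data.mean(1, keepdims=True) - data.mean(0) + grand) ** 2)
    ms_err = sse / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (
        ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    )


class TestICC:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2.5, 3.1, 4.0, 5.5, 6.0])
        res = icc_absolute(x, x)
        assert res.icc == pytest.approx(1.0, abs=1e-12)

    def test_toy_table_matches_anova_oracle(self):
        t1 = np.array([1.0, 2.0, 4.0, 6.0, 7.0])
        t2 = np.array([1.0, 3.0, 4.0, 5.0, 8.0])
        res = icc_absolute(t1, t2)
        assert res.icc == pytest.approx(anova_icc_oracle(t1, t2), abs=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        subj = rng.standard_normal(40)
        t1 = subj + 0.3 * rng.standard_normal(40)
        t2 = subj + 0.3 * rng.standard_normal(40) + 0.1
        res = icc_absolute(t1, t2)
        df = pd.DataFrame(
            {
                "subject": np.tile(np.arange(40), 2),
                "rater": np.repeat(["a", "b"], 40),
                "score": np.concatenate([t1, t2]),
            }
        )
        table = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        icc2 = table.loc[table["Type"] == "ICC(A,1)", "ICC"].iloc[0]
        assert res.icc == pytest.approx(icc2, abs=1e-6)

    def test_null_noise_near_zero(self):
        rng = np.random.default_rng(11)
        res = icc_absolute(rng.standard_normal(200), rng.standard_normal(200))
        assert abs(res.icc) < 0.15

    def test_ci_contains_estimate(self):
        rng = np.random.default_rng(2)
        subj = rng.standard_normal(30)
        res = icc_absolute(subj + 0.2 * rng.standard_normal(30),
                           subj + 0.2 * rng.standard_normal(30))
        assert res.ci_low <= res.icc <= res.ci_high
        assert res.icc <= 1.0

    def test_too_few_pairs(self):
        with pytest.raises(DataError):
            icc_absolute([1.0, 2.0], [1.0, 2.0])


class TestGroupCompare:
    def test_identical_groups_high_p(self, rng):
        base = rng.standard_normal(10)
        df = pd.DataFrame({"f": np.concatenate([base, base])})
        labels = np.repeat(["a", "b"], 10)
        out = group_compare(df, labels)
        assert out.loc["f", "p_value"] > 0.9

    def test_disjoint_groups(self, rng):
        df = pd.DataFrame({"f": np.concatenate([rng.random(10), rng.random(10) + 5])})
        labels = np.repeat(["a", "b"], 10)
        out = group_compare(df, labels)
        assert out.loc["f", "p_value"] < 0.001

    def test_u_statistic_matches_pair_counting(self, rng):
        a = rng.standard_normal(12)
        b = rng.standard_normal(15) + 0.4
        df = pd.DataFrame({"f": np.concatenate([a, b])})
        labels = np.array(["a"] * 12 + ["b"] * 15)
        out = group_compare(df, labels)
        wins = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        assert out.loc["f", "U"] == pytest.approx(wins, abs=1e-9)

    def test_two_groups_required(self, rng):
        df = pd.DataFrame({"f": rng.standard_normal(6)})
        with pytest.raises(ConfigurationError):
            group_compare(df, np.repeat(["a"], 6))
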